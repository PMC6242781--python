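product_id,label,dose_form,detected_species
YC01,Cistanches Herba,slice,Cynomorium songaricum
YC05,Cistanches Herba,slice,Cistanche deserticola
YC06,Cistanches Herba,slice,Cistanche tubulosa
YC09,Cistanches Herba,slice,Cistanche deserticola
YC11,Cistanches Herba,slice,Cistanche tubulosa
YC13,Cistanches Herba,slice,Salvia miltiorrhiza
YC17,Cistanches Herba,slice,Cistanche tubulosa
YC24,Cistanches Herba,slice,Cistanche deserticola
YC25,Cistanches Herba,slice,Cistanche deserticola
YC26,Cistanches Herba,slice,Cistanche tubulosa
YC27,Cistanches Herba,slice,Cistanche deserticola
YC28,Cistanches Herba,slice,Cistanche deserticola
YC29,Cistanches Herba,slice,Cistanche deserticola
YC30,Cistanches Herba,slice,Cistanche tubulosa
YC31,Cistanches Herba,slice,Cistanche deserticola
YC32,Cistanches Herba,slice,Cistanche deserticola
YC33,Cistanches Herba,slice,Cistanche tubulosa
YC34,Cistanches Herba,slice,Cistanche deserticola
YC35,Cistanches Herba,slice,Cistanche deserticola
YC36,Cistanches Herba,slice,Cistanche deserticola
YC37,Cistanches Herba,slice,Cistanche deserticola
YC38,Cistanches Herba,slice,Cistanche deserticola
YC39,Cistanches Herba,slice,Cistanche tubulosa
YC40,Cistanches Herba,slice,Cistanche tubulosa
YC41,Cistanches Herba,slice,Cistanche tubulosa
YC42,Cistanches Herba,slice,Cistanche tubulosa
YC43,Cistanches Herba,slice,Cistanche tubulosa
YC03,Cistanches Herba,powder,Cynomorium songaricum
YC04,Cistanches Herba,powder,Cistanche deserticola;Cistanche tubulosa;Cynomorium songaricum;Cistanche sinensis
YC18,Cistanches Herba,powder,Cistanche deserticola;Cistanche tubulosa;Cynomorium songaricum;Cistanche sinensis
YC19,Cistanches Herba,powder,Cistanche tubulosa;Cynomorium songaricum;Cistanche sinensis
YC20,Cistanches Herba,powder,Cistanche deserticola;Cistanche tubulosa;Cynomorium songaricum
YC21,Cistanches Herba,powder,Cistanche deserticola;Cistanche tubulosa;Cynomorium songaricum;Cistanche sinensis
YC22,Cistanches Herba,powder,Cistanche sinensis;Cistanche tubulosa;Cynomorium songaricum
YC23,Cistanches Herba,extract,Cistanche sinensis
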