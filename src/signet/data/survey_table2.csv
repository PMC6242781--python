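product_id,label,dose_form,detected_species
ZCY16,Shihu Yeguang pills,pill,Cynomorium songaricum;Cistanche deserticola
ZCY26,Shihu Yeguang pills,pill,Cynomorium songaricum
ZCY29,Wenweishu particles,particle,Cynomorium songaricum
ZCY33,Shihu Yeguang pills,pill,Cynomorium songaricum;Cistanche tubulosa
ZCY34,Shihu Yeguang pills,pill,Cistanche tubulosa
ZCY35,Sanbao capsules,capsule,Cynomorium songaricum;Cistanche deserticola;Cistanche sinensis
ZCY40,Kangguzhi Zengsheng pills,pill,Cynomorium songaricum
ZCY41,Kanggu Zengsheng pills,pill,Cynomorium songaricum;Cistanche tubulosa
ZCY44,Shihu Yeguang pills,pill,Cynomorium songaricum
ZCY48,Shihu Yeguang pills,pill,Cynomorium songaricum
ZCY51,Shihu Yeguang pills,pill,Cistanche tubulosa
ZCY53,Shihu Yeguang pills,pill,Cistanche deserticola
ZCY55,Shihu Yeguang pills,pill,Boschniakia rossica
ZCY56,Shihu Yeguang pills,pill,Cistanche tubulosa
ZCY57,Shihu Yeguang pills,pill,Boschniakia rossica
ZCY58,Shihu Yeguang pills,pill,Cistanche tubulosa
ZCY63,Yucong Qiangshen capsules,capsule,Cistanche deserticola;Cistanche tubulosa
ZCY64,Shihu Yeguang pills,pill,Cynomorium songaricum;Cistanche deserticola
ZCY65,Shihu Yeguang pills,pill,Cistanche deserticola
ZCY66,Wenweishu capsules,capsule,Cistanche deserticola
ZCY69,Shihu Yeguang pills,pill,Cistanche deserticola;Cistanche tubulosa
ZCY70,Shihu Yeguang pills,pill,Cistanche deserticola;Cistanche tubulosa
ZCY71,Shihu Yeguang pills,pill,Cistanche tubulosa
ZCY72,Shihu Yeguang pills,pill,Cistanche tubulosa
ZCY74,Shihu Yeguang pills,pill,Cynomorium songaricum;Cistanche tubulosa
ZCY79,Sanbao capsules,capsule,Cynomorium songaricum
ZCY85,Shihu Yeguang pills,pill,Cistanche tubulosa
ZCY92,Shihu Yeguang pills,pill,Cistanche tubulosa
ZCY94,Sanbao capsules,capsule,Cynomorium songaricum;Cistanche deserticola;Cistanche sinensis
ZCY95,Shihu Yeguang pills,pill,Cistanche tubulosa
ZCY96,Shihu Yeguang pills,pill,Cistanche tubulosa
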