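detected_species,mixture,ratio,cq_mean,cq_sd,detected
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,10,24.92,0.188,1
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,50,27.1,0.022,1
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,100,27.81,0.147,1
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,200,29.24,0.394,1
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,500,30.47,0.304,1
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,1000,31.39,0.561,1
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,2000,31.42,0.406,1
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,5000,32.46,0.862,1
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,10000,34.48,0.255,1
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,15000,35.83,0.328,1
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,20000,,,0
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,25000,,,0
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,30000,,,0
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,40000,,,0
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,50000,,,0
Cynomorium songaricum,Cistanche deserticola:Cynomorium songaricum,60000,,,0
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,10,23.64,0.078,1
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,50,26.00,0.101,1
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,100,27.07,0.155,1
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,200,28.26,0.109,1
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,500,29.46,0.066,1
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,1000,30.47,0.125,1
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,2000,31.36,0.101,1
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,5000,33.36,0.190,1
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,10000,34.33,0.214,1
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,15000,35.45,0.125,1
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,20000,36.26,0.756,1
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,25000,,,0
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,30000,,,0
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,40000,,,0
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,50000,,,0
Cistanche sinensis,Cistanche deserticola:Cistanche sinensis,60000,,,0
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,10,18.27,0.138,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,50,21.32,0.821,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,100,22.28,0.033,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,200,25.78,0.020,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,500,26.25,0.031,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,1000,27.22,0.052,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,2000,29.33,0.823,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,5000,30.45,0.262,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,10000,31.98,0.804,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,15000,32.79,0.361,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,20000,33.80,0.550,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,25000,35.46,0.886,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,30000,37.08,0.162,1
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,40000,,,0
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,50000,,,0
Boschniakia rossica,Cistanche deserticola:Boschniakia rossica,60000,,,0
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,10,19.07,0.022,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,50,21.34,0.030,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,100,22.53,0.105,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,200,23.77,0.111,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,500,25.16,0.089,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,1000,26.36,0.098,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,2000,27.30,0.164,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,5000,29.25,0.049,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,10000,30.01,0.260,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,15000,31.36,0.284,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,20000,32.84,0.338,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,25000,33.52,0.215,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,30000,36.38,0.459,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,40000,36.16,0.509,1
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,50000,,,0
Orobanche coerulescens,Cistanche deserticola:Orobanche coerulescens,60000,,,0
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,10,24.05,0.145,1
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,50,26.93,0.176,1
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,100,27.97,0.044,1
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,200,29.56,0.161,1
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,500,30.60,0.338,1
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,1000,31.18,0.090,1
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,2000,32.25,0.122,1
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,5000,33.70,0.222,1
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,10000,34.90,0.603,1
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,15000,35.95,0.470,1
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,20000,36.48,0.501,1
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,25000,,,0
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,30000,,,0
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,40000,,,0
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,50000,,,0
Cistanche tubulosa,Cistanche deserticola:Cistanche tubulosa,60000,,,0
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,10,23.93,0.165,1
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,50,25.06,0.155,1
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,100,26.25,0.093,1
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,200,28.05,0.085,1
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,500,29.07,0.163,1
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,1000,30.04,0.194,1
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,2000,31.82,0.107,1
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,5000,32.90,0.424,1
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,10000,35.17,0.183,1
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,15000,35.23,0.544,1
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,20000,36.25,0.279,1
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,25000,,,0
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,30000,,,0
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,40000,,,0
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,50000,,,0
Cistanche deserticola,Cistanche tubulosa:Cistanche deserticola,60000,,,0
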