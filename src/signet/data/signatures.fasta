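>sig_Cy_songaricum species=Cynomorium_songaricum length=30
CAATTATTTGAGGTGCATTGTAAGAAGCGT
>sig_Ci_sinensis species=Cistanche_sinensis length=34
CGATGGTCTCCCGTGCGCGAGGATGCACGGCCGG
>sig_B_rossica species=Boschniakia_rossica length=37
ACACTGGCCTCCCGTGCGCAACGACGTGCGGCCGGTC
>sig_O_coerulescens species=Orobanche_coerulescens length=31
GTCTGTCGTGTCGGATGGTGTTGCTTGTTGG
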