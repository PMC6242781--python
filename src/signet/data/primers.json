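[
  {
    "pair": 1,
    "name_f": "SYF1",
    "seq_f": "CTCAATGTGCTGCTGCTT",
    "name_r": "SYR1",
    "seq_r": "AGACTTACCGCTCACAATG",
    "target_species": "Cynomorium songaricum",
    "amplicon_size": 123,
    "anneal_temp": 50.0
  },
  {
    "pair": 2,
    "name_f": "HMRCF",
    "seq_f": "CCTTTAGGGTGATACTTAGGT",
    "name_r": "HMRCR",
    "seq_r": "CAGCACGAGAGTTGAGAG",
    "target_species": "Cistanche deserticola",
    "amplicon_size": 132,
    "anneal_temp": 50.0
  },
  {
    "pair": 3,
    "name_f": "GHRCF",
    "seq_f": "TTCTGGGACAATGCTTAGG",
    "name_r": "GHRCR",
    "seq_r": "CGACACGAGAGTTGAGTT",
    "target_species": "Cistanche tubulosa",
    "amplicon_size": 134,
    "anneal_temp": 50.0
  },
  {
    "pair": 4,
    "name_f": "SCRF",
    "seq_f": "ATATGGGCGATAGGTAGGT",
    "name_r": "SCRR",
    "seq_r": "GACAGCACGAGAGTTGAG",
    "target_species": "Cistanche sinensis",
    "amplicon_size": 131,
    "anneal_temp": 50.0
  },
  {
    "pair": 5,
    "name_f": "CCRF",
    "seq_f": "CGGTCCAAATACGATCCC",
    "name_r": "CCRR",
    "seq_r": "GACAGCACGAGAGTTGAG",
    "target_species": "Boschniakia rossica",
    "amplicon_size": 72,
    "anneal_temp": 50.0
  },
  {
    "pair": 6,
    "name_f": "LDF",
    "seq_f": "ATCTTCAACTCTCGTCTGTC",
    "name_r": "LDR",
    "seq_r": "CTCGTGCCTATGGGTCTA",
    "target_species": "Orobanche coerulescens",
    "amplicon_size": 71,
    "anneal_temp": 50.0
  }
]
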