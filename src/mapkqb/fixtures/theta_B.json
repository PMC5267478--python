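{
  "name": "theta_B",
  "seed": 7,
  "n_search": 50000,
  "theta": {
    "k1p": 4.607428816667128,
    "k2p": 0.5717143627034834,
    "k3p": 10.16998272977458,
    "k4p": 12.241632368761815,
    "k1m": 0.3213562508157396,
    "k2m": 4.111417509573276,
    "k3m": 0.22782195723332904,
    "k4m": 0.11535015558668432,
    "kFn": 1.519944730199073,
    "kFp": 4.227221592612389,
    "g": 5.742363568204128,
    "K": 2.969090920294398
  }
}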