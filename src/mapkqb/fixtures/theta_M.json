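{
  "name": "theta_M",
  "seed": 7,
  "n_search": 50000,
  "theta": {
    "k1p": 2.115952473416915,
    "k2p": 10.803740385169226,
    "k3p": 5.216157601863458,
    "k4p": 0.19274034107058638,
    "k1m": 0.3020095561366596,
    "k2m": 9.37580302831464,
    "k3m": 0.05160248813845654,
    "k4m": 6.852603686435523,
    "kFn": 14.16662766122491,
    "kFp": 1.8320714278323547,
    "g": 3.212129707277254,
    "K": 4.250929714652463
  }
}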