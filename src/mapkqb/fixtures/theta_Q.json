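{
  "name": "theta_Q",
  "seed": 7,
  "n_search": 50000,
  "theta": {
    "k1p": 2.7770722108874675,
    "k2p": 2.2688824735112627,
    "k3p": 0.32570605629701554,
    "k4p": 3.2292005823407646,
    "k1m": 0.387451781294019,
    "k2m": 0.28755408663830145,
    "k3m": 2.934500386767744,
    "k4m": 0.09207662569986115,
    "kFn": 0.9001987533345972,
    "kFp": 0.6391377126200583,
    "g": 3.51705432798066,
    "K": 4.3425270288049385
  }
}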