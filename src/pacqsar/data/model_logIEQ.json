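{
  "name": "rAhR_logIEQ_eq1",
  "response": "log IEQ",
  "intercept": -12.83,
  "terms": [
    {"descriptor": "SpMin2Bh(m)", "coef": 10.29},
    {"descriptor": "HATS5p", "coef": -9.03},
    {"descriptor": "sigma", "coef": -0.50},
    {"descriptor": "MATS5s", "coef": -6.82},
    {"descriptor": "H6e", "coef": -5.58},
    {"descriptor": "E2v", "coef": -20.30},
    {"descriptor": "SpMax8Bh(i)", "coef": 2.43}
  ]
}
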