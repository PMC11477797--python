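{
  "name": "rAhR_logTCDDmax_eq2",
  "response": "log %-TCDD-max",
  "intercept": -3.34,
  "terms": [
    {"descriptor": "HGM", "coef": -0.80},
    {"descriptor": "E_HOMO", "coef": -33.75},
    {"descriptor": "ATSC1e", "coef": 31.71}
  ]
}
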