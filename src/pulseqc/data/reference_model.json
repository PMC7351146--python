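{
  "standard_length": 15,
  "intercept": -10.8732,
  "weights": {
    "1": -9.6919,
    "3": 8.257,
    "4": 8.9216,
    "14": -7.9818
  },
  "decision_threshold": 0.5
}
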