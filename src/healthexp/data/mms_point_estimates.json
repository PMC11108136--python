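{
  "hle_mms": {
    "female": {"0": 39.94, "65": 2.43},
    "male": {"0": 42.87, "65": 2.17}
  },
  "le_mms": {
    "female": {"0": 85.82, "65": 22.31},
    "male": {"0": 80.58, "65": 18.86}
  }
}
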