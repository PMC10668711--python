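{
  "comment": "Confusion counts from the 177-min sound-only field comparison (4 sows); wrong-location pairs scored as false negatives. Switching the wrong-location policy moves the 1747 wrong-location pairs from FN to CP.",
  "policy": "wrong_as_FN",
  "CP": 1509,
  "FP": 10751,
  "FN": 1823,
  "CN": 1582,
  "wrong_location_pairs": 1747
}
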