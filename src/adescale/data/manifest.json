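{
  "total_records": 75,
  "records_per_class": {
    "monoclonal": 33,
    "polyclonal": 21,
    "non_antibody": 21
  },
  "drugs_per_class": {
    "monoclonal": 13,
    "polyclonal": 7,
    "non_antibody": 9
  },
  "sha256": "9f6ba8715e2c12ebfe2fff9fa70f0d2043f1f2f483b0a5de5083c1fe95e0f5bd"
}
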