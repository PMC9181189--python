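{
  "schema_version": 1,
  "feature_spec": ["tXT"],
  "omega0": -4.860,
  "omega1": 8.449,
  "omega2": null,
  "regularization": {"type": "L1", "C": 1.0, "lambda": 1.0},
  "fit_mode": "binary_label"
}
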