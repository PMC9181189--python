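{
  "schema_version": 1,
  "feature_spec": ["tXT", "tCS"],
  "omega0": -5.605,
  "omega1": 5.214,
  "omega2": 2.009,
  "regularization": {"type": "L1", "C": 1.0, "lambda": 1.0},
  "fit_mode": "binary_label"
}
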