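{
  "schema_version": 1,
  "feature_spec": ["tCS"],
  "omega0": -4.464,
  "omega1": 3.554,
  "omega2": null,
  "regularization": {"type": "L1", "C": 1.0, "lambda": 1.0},
  "fit_mode": "binary_label"
}
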