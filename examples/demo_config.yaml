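# Demo pipeline configuration: simulate a small three-layer dataset and run
# every stage end-to-end (inflamstate run --config examples/demo_config.yaml --out OUT).
seed: 1
simulate:
  n_features_per_class:
    TNF: 8
    IFN: 8
    COMMON: 8
    SYNERGY: 8
    "NULL": 8
  noise_sd: 0.2
thresholds:
  alpha: 0.05
  lfc_min: 1.0
baseline: ctrl_course
synergy_rule: s4_or_e3
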