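{
  "H-1": {
    "beams": ["H160", "H230"],
    "let_range_mev_cm": [3.0, 45.0],
    "probes": {
      "grain_4um": {"kb_ug_per_mev_cm2": 300.0, "kb_stderr": 20.0, "rl0": 1.13},
      "grain_38um": {"kb_ug_per_mev_cm2": 300.0, "kb_stderr": 30.0, "rl0": 1.09},
      "single_crystal": {"kb_ug_per_mev_cm2": 250.0, "kb_stderr": 30.0, "rl0": 0.856}
    }
  },
  "He-4": {
    "beams": ["He150"],
    "let_range_mev_cm": [20.0, 240.0],
    "probes": {
      "grain_4um": {"kb_ug_per_mev_cm2": 120.0, "kb_stderr": 30.0, "rl0": 1.3},
      "grain_38um": {"kb_ug_per_mev_cm2": 110.0, "kb_stderr": 35.0, "rl0": 1.2},
      "single_crystal": {"kb_ug_per_mev_cm2": 100.0, "kb_stderr": 42.0, "rl0": 0.78}
    }
  },
  "C-12": {
    "beams": ["C290", "C400"],
    "let_range_mev_cm": [90.0, 1700.0],
    "probes": {
      "grain_4um": {"kb_ug_per_mev_cm2": 1.8, "kb_stderr": 0.2, "rl0": 0.2},
      "grain_38um": {"kb_ug_per_mev_cm2": 1.7, "kb_stderr": 0.3, "rl0": 0.19},
      "single_crystal": {"kb_ug_per_mev_cm2": 2.5, "kb_stderr": 0.4, "rl0": 0.06}
    }
  }
}
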