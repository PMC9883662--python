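{
  "name": "riva_clarithromycin",
  "victim": "rivaroxaban",
  "analyte": "rivaroxaban",
  "perpetrator": "clarithromycin",
  "victim_regimen": {"dose_mg": 10.0, "interval_h": 24.0, "n_doses": 1, "start_offset_h": 48.0},
  "perpetrator_regimen": {"dose_mg": 500.0, "interval_h": 12.0, "n_doses": 5, "start_offset_h": 0.0},
  "t_end_h": 96.0,
  "auc_start_h": 48.0,
  "auc_end_h": 96.0
}
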