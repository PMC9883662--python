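{
  "_comment": "Verapamil perpetrator model: 2-compartment oral with fixed first-pass availability. Only its concentrations at the interaction sites matter; gut_free_fraction scales the luminal concentration that drives intestinal P-gp inhibition (dissolved fraction).",
  "name": "verapamil",
  "molecular_weight": 454.6,
  "fu_plasma": 0.1,
  "absorption": {
    "ka_h": 1.15,
    "lag_h": 0.25,
    "gut_segments": 7,
    "transit_time_h": 3.32,
    "first_pass_availability": 0.22,
    "gut_free_fraction": 0.03,
    "v_lumen_total_L": 0.25,
    "source": "immediate-release; high hepatic first pass; gut_free_fraction calibrated"
  },
  "distribution": {
    "vc_L_per_kg": 1.5,
    "vp_L_per_kg": 3.0,
    "q_inter_L_h": 60.0
  },
  "clearance": {
    "systemic_cl_L_h": 55.0,
    "renal_filtration": false,
    "source": "high-clearance; literature-typical"
  }
}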