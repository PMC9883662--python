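{
  "_comment": "Ketoconazole perpetrator model: strong CYP3A4 inhibitor (very low unbound Ki), strong P-gp inhibitor.",
  "name": "ketoconazole",
  "molecular_weight": 531.4,
  "fu_plasma": 0.015,
  "absorption": {
    "ka_h": 1.4,
    "lag_h": 0.2,
    "gut_segments": 7,
    "transit_time_h": 3.32,
    "first_pass_availability": 0.80,
    "gut_free_fraction": 0.03,
    "v_lumen_total_L": 0.25
  },
  "distribution": {
    "vc_L_per_kg": 0.3,
    "vp_L_per_kg": 0.2,
    "q_inter_L_h": 25.0
  },
  "clearance": {
    "systemic_cl_L_h": 9.0,
    "renal_filtration": false
  }
}
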