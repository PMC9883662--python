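{
  "_comment": "Fluconazole perpetrator model: near-complete availability, low clearance, long half-life; inhibits CYP3A4 only.",
  "name": "fluconazole",
  "molecular_weight": 306.3,
  "fu_plasma": 0.89,
  "absorption": {
    "ka_h": 1.0,
    "lag_h": 0.2,
    "gut_segments": 7,
    "transit_time_h": 3.32,
    "first_pass_availability": 0.96,
    "gut_free_fraction": 1.0,
    "v_lumen_total_L": 0.25
  },
  "distribution": {
    "vc_L_per_kg": 0.35,
    "vp_L_per_kg": 0.25,
    "q_inter_L_h": 20.0
  },
  "clearance": {
    "systemic_cl_L_h": 1.0,
    "renal_filtration": false
  }
}
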