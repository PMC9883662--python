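{
  "_comment": "Clarithromycin perpetrator model (competitive-equivalent inhibition; the package does not represent mechanism-based inactivation, so the effective Ki values in interactions.json are calibrated).",
  "name": "clarithromycin",
  "molecular_weight": 748.0,
  "fu_plasma": 0.30,
  "absorption": {
    "ka_h": 0.7,
    "lag_h": 0.25,
    "gut_segments": 7,
    "transit_time_h": 3.32,
    "first_pass_availability": 0.55,
    "gut_free_fraction": 0.03,
    "v_lumen_total_L": 0.25
  },
  "distribution": {
    "vc_L_per_kg": 2.0,
    "vp_L_per_kg": 1.0,
    "q_inter_L_h": 30.0
  },
  "clearance": {
    "systemic_cl_L_h": 32.0,
    "renal_filtration": false
  }
}
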