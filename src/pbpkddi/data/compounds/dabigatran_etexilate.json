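{
  "_comment": "Dabigatran etexilate (prodrug). Reconstruction: structural values from literature-typical ranges; absorption/P-gp/CES terms calibrated jointly so net dabigatran bioavailability (~3-7%), adult exposure and the clinical interaction magnitudes with verapamil/clarithromycin are reproduced by the reduced gut model.",
  "name": "dabigatran_etexilate",
  "molecular_weight": 627.7,
  "fu_plasma": 0.04,
  "blood_to_plasma": 1.0,
  "absorption": {
    "ka_h": 0.015,
    "lag_h": 0.4,
    "gut_segments": 7,
    "transit_time_h": 3.32,
    "k_ent_h": 40.0,
    "fraction_released": 1.0,
    "v_lumen_total_L": 0.25,
    "v_ent_total_L": 0.07,
    "source": "ka/k_ent calibrated; transit literature-typical small-intestinal residence"
  },
  "pgp_gut": {
    "km_uM": 100.0,
    "jmax_mg_h": 150.0,
    "basis": "whole_gut",
    "source": "calibrated; Jmax expressed per reference whole gut, scaled by intestinal P-gp abundance"
  },
  "distribution": {
    "vc_L_per_kg": 1.0,
    "vp_L_per_kg": 1.0,
    "q_inter_L_h": 20.0,
    "kp_liver": 2.0,
    "source": "lumped; prodrug plasma levels are transient and near-negligible"
  },
  "clearance": {
    "clint_L_h": {
      "CES": 4700.0
    },
    "renal_filtration": true,
    "source": "hepatic carboxylesterase conversion only; calibrated to a high first-pass extraction"
  },
  "metabolite_links": [
    {
      "child": "dabigatran",
      "formation_fraction": 1.0,
      "pathway": "CES"
    }
  ]
}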