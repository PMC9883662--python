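{
  "_comment": "Rivaroxaban. Two-thirds hepatic metabolism (CYP3A4 fm 0.37, CYP2J2 fm 0.29 via retrograde split), one-third renal, mostly active secretion (renal P-gp + OAT3). Dose-dependent oral availability via a threshold rule on fraction released.",
  "name": "rivaroxaban",
  "molecular_weight": 435.9,
  "fu_plasma": 0.007,
  "blood_to_plasma": 0.7,
  "absorption": {
    "ka_h": 1.2,
    "lag_h": 0.3,
    "gut_segments": 7,
    "transit_time_h": 3.32,
    "k_ent_h": 10.0,
    "fraction_released": 0.96,
    "v_lumen_total_L": 0.25,
    "v_ent_total_L": 0.07,
    "source": "fast, nearly complete absorption; calibrated"
  },
  "pgp_gut": {
    "km_uM": 3.0,
    "jmax_mg_h": 2.0,
    "basis": "whole_gut",
    "source": "calibrated; saturated at therapeutic luminal concentrations"
  },
  "bioavailability_rule": {
    "f_low_dose": 0.96,
    "f_high_dose": 0.72,
    "dose_threshold_mg": 10.0,
    "source": "calibrated so net F is ~0.9 at <=10 mg and ~0.66 above"
  },
  "distribution": {
    "vc_L_per_kg": 0.4,
    "vp_L_per_kg": 0.35,
    "q_inter_L_h": 15.0,
    "source": "Vss ~0.75 L/kg"
  },
  "clearance": {
    "clint_L_h": {"CYP3A4": 306.0, "CYP2J2": 241.0, "OTHER": 8.0},
    "fm": {"CYP3A4": 0.37, "CYP2J2": 0.29},
    "renal_filtration": true,
    "renal_secretion_L_h": 2.0,
    "secretion_split": {"PGP_RENAL": 0.7, "OAT3": 0.3},
    "source": "retrograde split of hepatic CLint by fm; renal secretion at reference GFR 100 mL/min; calibrated to total CL ~6.5 L/h in Caucasian adults"
  },
  "metabolite_links": []
}
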