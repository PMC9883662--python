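{
  "_comment": "Competitive inhibition constants (uM) per perpetrator and target. PGP_GUT Ki values are referenced to the luminal driving concentration (after the perpetrator's gut_free_fraction) and are calibrated, with mechanism-based components folded into a competitive equivalent where the literature mechanism is not purely reversible.",
  "verapamil": {
    "PGP_GUT": 0.15,
    "PGP_RENAL": 2.0,
    "CYP3A4": 15.0
  },
  "clarithromycin": {
    "PGP_GUT": 22.0,
    "PGP_RENAL": 0.15,
    "CYP3A4": 0.1
  },
  "fluconazole": {
    "CYP3A4": 10.0
  },
  "ketoconazole": {
    "PGP_GUT": 2.0,
    "PGP_RENAL": 0.02,
    "CYP3A4": 0.004,
    "CYP2J2": 0.02
  }
}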