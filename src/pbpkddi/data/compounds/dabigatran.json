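{
  "_comment": "Dabigatran (active moiety). Predominantly renally filtered (fu*GFR); 20% of elimination is UGT2B15 glucuronidation to the active glucuronide at the reference adult physiology.",
  "name": "dabigatran",
  "molecular_weight": 471.5,
  "fu_plasma": 0.65,
  "blood_to_plasma": 1.0,
  "distribution": {
    "vc_L_per_kg": 0.35,
    "vp_L_per_kg": 0.35,
    "q_inter_L_h": 60.0,
    "source": "Vss ~0.9 L/kg, literature-typical"
  },
  "clearance": {
    "clint_L_h": {
      "UGT2B15": 1.5
    },
    "renal_filtration": true,
    "source": "UGT2B15 CLint calibrated so glucuronide formation is 20% of total elimination at reference adult GFR"
  },
  "metabolite_links": [
    {
      "child": "dabigatran_glucuronide",
      "formation_fraction": 1.0,
      "pathway": "UGT2B15"
    }
  ]
}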