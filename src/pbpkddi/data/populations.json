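{
  "_comment": "Ethnicity-specific covariate models for the virtual population generator. Aging coefficients are reconstructions calibrated so monotherapy exposure in older age groups rises in the clinically reported range; see docs/methods.md.",
  "Chinese": {
    "anthropometrics": {
      "M": {
        "height_cm": 169.0,
        "height_sd_cm": 5.8,
        "bmi": 22.8,
        "serum_creatinine_ref": 0.85,
        "hematocrit": 0.45
      },
      "F": {
        "height_cm": 158.0,
        "height_sd_cm": 5.4,
        "bmi": 22.2,
        "serum_creatinine_ref": 0.7,
        "hematocrit": 0.4
      }
    },
    "weight_cv": 0.13,
    "height_decline_onset_years": 60.0,
    "height_decline_cm_per_year": 0.1,
    "cardiac_index_ref": 3.35,
    "cardiac_index_ref_age": 25.0,
    "cardiac_index_decline_per_year": 0.011,
    "creatinine_rise_per_year": 0.0065,
    "creatinine_cv": 0.1,
    "bsa_ref": 1.7,
    "liver_volume_ref": 1.7,
    "liver_decline_onset_years": 40.0,
    "liver_decline_per_year": 0.003,
    "kidney_volume_ref": 0.3,
    "gut_volume_ref": 1.1,
    "liver_flow_fraction": 0.245,
    "kidney_flow_fraction": 0.19,
    "gut_flow_fraction": 0.14,
    "abundance_cv": 0.22,
    "abundance_aging": {},
    "creatinine_plateau_age": 71.0
  },
  "Caucasian": {
    "anthropometrics": {
      "M": {
        "height_cm": 176.5,
        "height_sd_cm": 6.3,
        "bmi": 24.6,
        "serum_creatinine_ref": 0.9,
        "hematocrit": 0.45
      },
      "F": {
        "height_cm": 163.2,
        "height_sd_cm": 5.9,
        "bmi": 24.0,
        "serum_creatinine_ref": 0.74,
        "hematocrit": 0.4
      }
    },
    "weight_cv": 0.15,
    "height_decline_onset_years": 60.0,
    "height_decline_cm_per_year": 0.1,
    "cardiac_index_ref": 3.35,
    "cardiac_index_ref_age": 25.0,
    "cardiac_index_decline_per_year": 0.011,
    "creatinine_rise_per_year": 0.0065,
    "creatinine_cv": 0.1,
    "bsa_ref": 1.86,
    "liver_volume_ref": 1.95,
    "liver_decline_onset_years": 40.0,
    "liver_decline_per_year": 0.003,
    "kidney_volume_ref": 0.33,
    "gut_volume_ref": 1.2,
    "liver_flow_fraction": 0.245,
    "kidney_flow_fraction": 0.19,
    "gut_flow_fraction": 0.14,
    "abundance_cv": 0.22,
    "abundance_aging": {},
    "creatinine_plateau_age": 71.0
  }
}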