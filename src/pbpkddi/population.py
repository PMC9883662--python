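"""Virtual population generator with aging-dependent physiology.

Samples Caucasian or Chinese adult and geriatric subjects with the
covariates the whole-body model needs: anthropometrics, cardiac output,
organ volumes and blood flows, serum creatinine, glomerular filtration
rate (Cockcroft–Gault creatinine clearance as the GFR surrogate) and
lognormally distributed enzyme/transporter abundance scalars.

The geriatric covariate models are deliberately simple reconstructions:
linear height decline after 60, a linear fall in cardiac index with age,
a linear rise in serum creatinine, and a slow loss of liver volume after
40.  Coefficients live in the bundled ``populations.json`` and are
ethnicity-specific; all of them can be overridden by passing a custom
configuration mapping.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

Ethnicity = Literal["Caucasian", "Chinese"]
Sex = Literal["M", "F"]

#: enzyme / transporter slots every profile carries a scalar for
ABUNDANCE_KEYS = ("CYP3A4", "CYP2J2", "CES", "UGT2B15", "PGP_GUT", "PGP_RENAL", "OAT3")

#: reference glomerular filtration rate (mL/min) that renal secretion
#: clearances in the compound files are expressed against
GFR_REFERENCE_ML_MIN = 100.0

#: reference liver volume (L) that hepatic intrinsic clearances in the
#: compound files are expressed against
LIVER_VOLUME_REFERENCE_L = 1.80


class ConfigurationError(ValueError):
    """Invalid demographic or population configuration."""


class DomainError(ValueError):
    """Input outside the physiological domain of a covariate formula."""


class DemographicSpec(BaseModel):
    """One arm's demographic definition (ethnicity, age range, size)."""

    ethnicity: Ethnicity
    age_min: float = Field(ge=18)
    age_max: float
    proportion_female: float = Field(default=0.5, ge=0.0, le=1.0)
    n_subjects: int = Field(ge=1)

    @model_validator(mode="after")
    def _check_ages(self) -> "DemographicSpec":
        if self.age_max < self.age_min:
            raise ConfigurationError(
                f"age_max ({self.age_max}) < age_min ({self.age_min})"
            )
        return self


class PhysiologyProfile(BaseModel):
    """A single virtual subject, fully determining one simulation."""

    subject_id: int
    age: float
    sex: Sex
    ethnicity: Ethnicity
    weight: float = Field(gt=0)  # kg
    height: float = Field(gt=0)  # cm
    bsa: float = Field(gt=0)  # m^2
    cardiac_output: float = Field(gt=0)  # L/h
    organ_volumes: dict[str, float]  # L
    organ_blood_flows: dict[str, float]  # L/h
    hematocrit: float = Field(gt=0, lt=1)
    serum_creatinine: float = Field(gt=0)  # mg/dL
    gfr: float = Field(gt=0)  # mL/min
    abundance_scalars: dict[str, float]

    @model_validator(mode="after")
    def _check_physiology(self) -> "PhysiologyProfile":
        if any(v <= 0 for v in self.organ_volumes.values()):
            raise DomainError("organ volumes must be strictly positive")
        if any(q < 0 for q in self.organ_blood_flows.values()):
            raise DomainError("organ blood flows must be non-negative")
        named = sum(
            q for k, q in self.organ_blood_flows.items() if k != "rest"
        )
        if named > self.cardiac_output * (1 + 1e-9):
            raise DomainError("sum of organ blood flows exceeds cardiac output")
        if any(s <= 0 for s in self.abundance_scalars.values()):
            raise DomainError("abundance scalars must be strictly positive")
        return self


def body_surface_area(weight: float, height: float) -> float:
    """Du Bois body surface area (m^2) from weight (kg) and height (cm).

    BSA = 0.007184 * W^0.425 * H^0.725
    """
    if weight <= 0 or height <= 0:
        raise DomainError("weight and height must be positive")
    return 0.007184 * weight**0.425 * height**0.725


def gfr_from_creatinine(
    age: float, weight: float, sex: Sex, serum_creatinine: float
) -> float:
    """Cockcroft–Gault creatinine clearance (mL/min), used as the GFR surrogate.

    CrCL = (140 - age) * weight / (72 * Scr), times 0.85 for women.
    """
    if age <= 0 or weight <= 0 or serum_creatinine <= 0:
        raise DomainError("age, weight and serum creatinine must be positive")
    if age >= 140:
        raise DomainError("Cockcroft-Gault is undefined for age >= 140")
    gfr = (140.0 - age) * weight / (72.0 * serum_creatinine)
    if sex == "F":
        gfr *= 0.85
    return gfr


def _load_default_config() -> dict:
    with resources.files("pbpkddi.data").joinpath("populations.json").open() as fh:
        return json.load(fh)


_DEFAULT_CONFIG: dict | None = None


def default_population_config() -> dict:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = _load_default_config()
    return _DEFAULT_CONFIG


def _sample_subject(
    idx: int,
    spec: DemographicSpec,
    cfg: dict,
    rng: np.random.Generator,
) -> PhysiologyProfile:
    age = float(rng.uniform(spec.age_min, spec.age_max))
    sex: Sex = "F" if rng.random() < spec.proportion_female else "M"
    sexcfg = cfg["anthropometrics"][sex]

    height_mean = sexcfg["height_cm"]
    if age > cfg["height_decline_onset_years"]:
        height_mean -= cfg["height_decline_cm_per_year"] * (
            age - cfg["height_decline_onset_years"]
        )
    height = float(rng.normal(height_mean, sexcfg["height_sd_cm"]))
    height = max(height, 120.0)

    bmi = sexcfg["bmi"]
    weight = float(bmi * (height / 100.0) ** 2 * rng.lognormal(0.0, cfg["weight_cv"]))
    weight = max(weight, 30.0)
    bsa = body_surface_area(weight, height)

    # cardiac index (L/min/m^2) declines linearly with age
    ci = cfg["cardiac_index_ref"] - cfg["cardiac_index_decline_per_year"] * (
        age - cfg["cardiac_index_ref_age"]
    )
    ci = max(ci, 1.2)
    cardiac_output = ci * bsa * 60.0  # L/h

    # creatinine rises with age but plateaus in the very old (sarcopenia:
    # muscle mass falls roughly in step with true filtration)
    scr_age = min(age, cfg.get("creatinine_plateau_age", 200.0))
    scr = (
        sexcfg["serum_creatinine_ref"]
        * (1.0 + cfg["creatinine_rise_per_year"] * (scr_age - 20.0))
        * rng.lognormal(0.0, cfg["creatinine_cv"])
    )
    gfr = gfr_from_creatinine(age, weight, sex, scr)

    bsa_scale = bsa / cfg["bsa_ref"]
    liver = cfg["liver_volume_ref"] * bsa_scale
    if age > cfg["liver_decline_onset_years"]:
        liver *= 1.0 - cfg["liver_decline_per_year"] * (
            age - cfg["liver_decline_onset_years"]
        )
    liver = max(liver, 0.5)
    kidney = cfg["kidney_volume_ref"] * bsa_scale
    hematocrit = sexcfg["hematocrit"]
    plasma = 0.0435 * weight
    blood = plasma / (1.0 - hematocrit)
    gut = cfg["gut_volume_ref"] * bsa_scale
    rest = max(weight * 0.95 - (liver + kidney + blood + gut), 1.0)

    q_liver = cfg["liver_flow_fraction"] * cardiac_output
    q_kidney = cfg["kidney_flow_fraction"] * cardiac_output
    q_gut = cfg["gut_flow_fraction"] * cardiac_output
    q_rest = max(cardiac_output - q_liver - q_kidney, 0.0)

    cv = cfg["abundance_cv"]
    aging = cfg.get("abundance_aging", {})
    scalars: dict[str, float] = {}
    for key in ABUNDANCE_KEYS:
        mean = 1.0
        decline = aging.get(key)
        if decline:
            onset = decline.get("onset_years", 20.0)
            if age > onset:
                mean *= max(
                    1.0 - decline["fraction_per_decade"] * (age - onset) / 10.0,
                    0.05,
                )
        scalars[key] = float(mean * rng.lognormal(0.0, cv))

    return PhysiologyProfile(
        subject_id=idx,
        age=age,
        sex=sex,
        ethnicity=spec.ethnicity,
        weight=weight,
        height=height,
        bsa=bsa,
        cardiac_output=cardiac_output,
        organ_volumes={
            "gut": gut,
            "liver": liver,
            "kidney": kidney,
            "blood": blood,
            "plasma": plasma,
            "rest": rest,
        },
        organ_blood_flows={
            "liver": q_liver,
            "kidney": q_kidney,
            "gut": q_gut,
            "rest": q_rest,
        },
        hematocrit=hematocrit,
        serum_creatinine=scr,
        gfr=gfr,
        abundance_scalars=scalars,
    )


def sample_population(
    spec: DemographicSpec,
    seed: int,
    config: dict | None = None,
) -> list[PhysiologyProfile]:
    """Draw ``spec.n_subjects`` virtual subjects, reproducibly from ``seed``.

    The per-ethnicity covariate configuration defaults to the bundled
    ``populations.json``; pass ``config`` (same structure) to override.
    """
    full = config if config is not None else default_population_config()
    if spec.ethnicity not in full:
        raise ConfigurationError(f"no population configuration for {spec.ethnicity!r}")
    cfg = full[spec.ethnicity]
    rng = np.random.default_rng(seed)
    return [_sample_subject(i, spec, cfg, rng) for i in range(spec.n_subjects)]


def reference_subject(
    ethnicity: Ethnicity = "Chinese",
    age: float = 40.0,
    sex: Sex = "M",
    config: dict | None = None,
    subject_id: int = 0,
) -> PhysiologyProfile:
    """A deterministic subject at the covariate means (no inter-individual
    variability); used for sensitivity sweeps and analytic checks."""

    class _MeanRng:
        def uniform(self, lo, hi):
            return age

        def random(self):
            return 1.0 if sex == "M" else 0.0

        def normal(self, mean, sd):
            return mean

        def lognormal(self, mu, sigma):
            return 1.0

    full = config if config is not None else default_population_config()
    if ethnicity not in full:
        raise ConfigurationError(f"no population configuration for {ethnicity!r}")
    spec = DemographicSpec(
        ethnicity=ethnicity,
        age_min=max(age, 18.0),
        age_max=max(age, 18.0),
        proportion_female=0.5,
        n_subjects=1,
    )
    return _sample_subject(subject_id, spec, full[ethnicity], _MeanRng())


def population_to_frame(profiles: list[PhysiologyProfile]):
    """Flatten a sampled population into a tidy DataFrame (one row per subject)."""
    import pandas as pd

    rows = []
    for p in profiles:
        row = {
            "subject_id": p.subject_id,
            "age_years": p.age,
            "sex": p.sex,
            "ethnicity": p.ethnicity,
            "weight_kg": p.weight,
            "height_cm": p.height,
            "bsa_m2": p.bsa,
            "cardiac_output_L_h": p.cardiac_output,
            "hematocrit": p.hematocrit,
            "serum_creatinine_mg_dL": p.serum_creatinine,
            "gfr_mL_min": p.gfr,
        }
        row.update({f"v_{k}_L": v for k, v in p.organ_volumes.items()})
        row.update({f"q_{k}_L_h": v for k, v in p.organ_blood_flows.items()})
        row.update({f"ab_{k}": v for k, v in p.abundance_scalars.items()})
        rows.append(row)
    return pd.DataFrame(rows)
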