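"""Virtual DDI clinical studies: paired with/without-perpetrator arms.

A study follows the trial design used for geriatric extrapolation: a
number of trials (default 10) of a number of subjects each (default 10)
sampled from one demographic group.  Every subject is simulated twice —
victim alone and victim plus perpetrator — with identical physiology, so
the exposure ratio is paired within subject.  Results carry per-subject
metrics, per-trial geometric means and the pooled geometric-mean ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import metrics as mx
from .compounds import (
    CompoundModel,
    InteractionParameters,
    load_bundled_chain,
    load_bundled_compound,
    load_interactions,
)
from .engine import ConcentrationTimeProfile, simulate_subject
from .population import DemographicSpec, PhysiologyProfile, sample_population

__all__ = [
    "Regimen",
    "TrialDesign",
    "Scenario",
    "DDIStudyResult",
    "SafetyResult",
    "staggered_regimen",
    "run_ddi_study",
    "run_scenario_study",
    "run_steady_state_safety",
    "sensitivity_sweep",
    "load_scenario",
    "analyte_concentration",
]

#: solver settings used for population-scale trial runs
TRIAL_SOLVER_OPTS = {"rtol": 1e-6, "atol": 1e-9, "dt": 0.25}


@dataclass(frozen=True)
class Regimen:
    compound: str
    dose_mg: float
    interval_h: float = 24.0
    n_doses: int = 1
    start_offset_h: float = 0.0

    def __post_init__(self):
        if self.dose_mg < 0:
            raise ValueError("dose must be >= 0")
        if self.interval_h <= 0:
            raise ValueError("interval must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.start_offset_h < 0:
            raise ValueError("start offset must be >= 0")

    @property
    def last_dose_time_h(self) -> float:
        return self.start_offset_h + (self.n_doses - 1) * self.interval_h


def staggered_regimen(base: Regimen, stagger_h: float) -> Regimen:
    """Shift the victim regimen by +stagger hours relative to the perpetrator."""
    if stagger_h < 0:
        raise ValueError("stagger must be >= 0")
    return Regimen(
        compound=base.compound,
        dose_mg=base.dose_mg,
        interval_h=base.interval_h,
        n_doses=base.n_doses,
        start_offset_h=base.start_offset_h + stagger_h,
    )


class TrialDesign(BaseModel):
    n_trials: int = Field(default=10, ge=1)
    n_subjects_per_trial: int = Field(default=10, ge=1)
    demographics: DemographicSpec
    master_seed: int = 0

    def sample_subjects(self) -> list[PhysiologyProfile]:
        spec = self.demographics.model_copy(
            update={"n_subjects": self.n_trials * self.n_subjects_per_trial}
        )
        return sample_population(spec, seed=self.master_seed)


class Scenario(BaseModel):
    """A named victim/perpetrator study definition (bundled or user file)."""

    name: str
    victim: str  # parent compound short name (file stem)
    analyte: str  # which analyte's exposure the ratio is computed on
    perpetrator: str | None = None
    victim_regimen: dict
    perpetrator_regimen: dict | None = None
    t_end_h: float
    auc_start_h: float = 0.0
    auc_end_h: float | None = None

    def victim_reg(self) -> Regimen:
        return Regimen(compound=self.victim, **self.victim_regimen)

    def perpetrator_reg(self) -> Regimen | None:
        if self.perpetrator is None or self.perpetrator_regimen is None:
            return None
        return Regimen(compound=self.perpetrator, **self.perpetrator_regimen)


def load_scenario(name_or_path: str | Path) -> Scenario:
    p = Path(name_or_path)
    if p.exists():
        return Scenario.model_validate(json.loads(p.read_text()))
    ref = resources.files("pbpkddi.data.scenarios").joinpath(f"{name_or_path}.json")
    with resources.as_file(ref) as path:
        if not Path(path).exists():
            raise FileNotFoundError(f"no scenario {name_or_path!r}")
        return Scenario.model_validate(json.loads(Path(path).read_text()))


def analyte_concentration(
    profiles: dict[str, ConcentrationTimeProfile], analyte: str
) -> tuple[np.ndarray, np.ndarray]:
    """Times and ng/mL for an analyte.

    ``total_dabigatran`` is the active moiety the clinical assay reports:
    dabigatran plus its glucuronide expressed in dabigatran mass
    equivalents (the conjugate is cleaved before quantification, so its
    concentration counts at the parent's molecular weight).
    """
    if analyte == "total_dabigatran":
        dab = profiles["dabigatran"]
        dabg = profiles.get("dabigatran_glucuronide")
        conc = dab.conc_ng_ml.copy()
        if dabg is not None:
            conc = conc + dabg.conc_ng_ml * (471.5 / 647.6)
        return dab.times, conc
    p = profiles[analyte]
    return p.times, p.conc_ng_ml


@dataclass
class DDIStudyResult:
    """Paired exposure metrics and geometric-mean ratios of one study."""

    analyte: str
    metric: str
    subjects: pd.DataFrame  # trial, subject, alone, combined, ratio
    pooled_ratio: float
    trial_ratios: list[float]
    ratio_range_trials: tuple[float, float]
    ratio_range_subjects: tuple[float, float]
    pooled_alone: float = float("nan")
    pooled_combined: float = float("nan")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "analyte": [self.analyte],
                "metric": [self.metric],
                "n_subjects": [len(self.subjects)],
                "pooled_gm_ratio": [self.pooled_ratio],
                "trial_ratio_min": [self.ratio_range_trials[0]],
                "trial_ratio_max": [self.ratio_range_trials[1]],
                "subject_ratio_min": [self.ratio_range_subjects[0]],
                "subject_ratio_max": [self.ratio_range_subjects[1]],
                "gm_alone": [self.pooled_alone],
                "gm_combined": [self.pooled_combined],
            }
        )


def _exposure(profiles, analyte, metric, window) -> float:
    t, c = analyte_concentration(profiles, analyte)
    lo, hi = window
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if metric == "auc":
        return mx.auc_trapezoid(t[mask], c[mask])
    if metric == "cmax":
        return float(np.max(c[mask]))
    raise ValueError(f"unknown metric {metric!r}")


def run_ddi_study(
    design: TrialDesign,
    victims: list[CompoundModel],
    victim_regimen: Regimen,
    perpetrator: CompoundModel | None,
    perpetrator_regimen: Regimen | None,
    interactions: InteractionParameters | None,
    t_end: float,
    analyte: str,
    metric: str = "auc",
    auc_window: tuple[float, float] | None = None,
    solver_opts: dict | None = None,
    ratio_mode: str = "geometric",
) -> DDIStudyResult:
    """Simulate victim-alone vs victim+perpetrator in the same subjects.

    When ``perpetrator`` is None the combined arm repeats the alone arm
    and the pooled ratio is exactly 1.
    """
    if perpetrator is not None and interactions is None:
        raise ValueError("perpetrator given without interaction parameters")
    opts = dict(TRIAL_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    window = auc_window or (0.0, t_end)
    profiles_pop = design.sample_subjects()

    rows = []
    for idx, prof in enumerate(profiles_pop):
        trial = idx // design.n_subjects_per_trial
        alone = simulate_subject(
            prof, victims, None, None, [victim_regimen], t_end, opts
        )
        m_alone = _exposure(alone, analyte, metric, window)
        if perpetrator is None:
            m_comb = m_alone
        else:
            combined = simulate_subject(
                prof,
                victims,
                perpetrator,
                interactions,
                [victim_regimen, perpetrator_regimen],
                t_end,
                opts,
            )
            m_comb = _exposure(combined, analyte, metric, window)
        rows.append(
            {
                "trial": trial,
                "subject": prof.subject_id,
                "alone": m_alone,
                "combined": m_comb,
                "ratio": m_comb / m_alone,
            }
        )
    df = pd.DataFrame(rows)

    def pool(ratios: np.ndarray) -> float:
        if ratio_mode == "geometric":
            return float(np.exp(np.mean(np.log(ratios))))
        return float(np.mean(ratios))

    trial_ratios = [pool(g["ratio"].to_numpy()) for _, g in df.groupby("trial")]
    pooled = pool(df["ratio"].to_numpy())
    return DDIStudyResult(
        analyte=analyte,
        metric=metric,
        subjects=df,
        pooled_ratio=pooled,
        trial_ratios=trial_ratios,
        ratio_range_trials=(min(trial_ratios), max(trial_ratios)),
        ratio_range_subjects=(float(df["ratio"].min()), float(df["ratio"].max())),
        pooled_alone=float(np.exp(np.mean(np.log(df["alone"])))),
        pooled_combined=float(np.exp(np.mean(np.log(df["combined"])))),
    )


def run_scenario_study(
    scenario: Scenario,
    design: TrialDesign,
    interactions: dict[str, InteractionParameters] | None = None,
    solver_opts: dict | None = None,
) -> DDIStudyResult:
    """Convenience wrapper resolving bundled compounds for a scenario."""
    victims = load_bundled_chain(scenario.victim)
    perp = None
    inter = None
    if scenario.perpetrator is not None:
        perp = load_bundled_compound(scenario.perpetrator)
        table = interactions if interactions is not None else load_interactions()
        inter = table[scenario.perpetrator]
    return run_ddi_study(
        design,
        victims,
        scenario.victim_reg(),
        perp,
        scenario.perpetrator_reg(),
        inter,
        t_end=scenario.t_end_h,
        analyte=scenario.analyte,
        auc_window=(scenario.auc_start_h, scenario.auc_end_h or scenario.t_end_h),
        solver_opts=solver_opts,
    )


@dataclass
class SafetyResult:
    """Steady-state trough concentrations against bleeding thresholds."""

    analyte: str
    trough_time_h: float
    troughs_ng_ml: pd.DataFrame  # trial, subject, trough
    median: float
    iqr: tuple[float, float]
    thresholds_ng_ml: dict[str, float] = field(default_factory=dict)

    def exceeds(self) -> dict[str, bool]:
        return {k: self.median > v for k, v in self.thresholds_ng_ml.items()}

    def summary(self) -> pd.DataFrame:
        row = {
            "analyte": self.analyte,
            "trough_time_h": self.trough_time_h,
            "median_ng_ml": self.median,
            "iqr_low": self.iqr[0],
            "iqr_high": self.iqr[1],
        }
        for k, v in self.thresholds_ng_ml.items():
            row[f"threshold_{k}"] = v
            row[f"median_exceeds_{k}"] = self.median > v
        return pd.DataFrame([row])


def run_steady_state_safety(
    design: TrialDesign,
    victims: list[CompoundModel],
    victim_regimen: Regimen,
    perpetrator: CompoundModel | None,
    perpetrator_regimen: Regimen | None,
    interactions: InteractionParameters | None,
    duration_days: float = 10.0,
    trough_time_h: float = 216.0,
    analyte: str = "total_dabigatran",
    thresholds_ng_ml: dict[str, float] | None = None,
    solver_opts: dict | None = None,
) -> SafetyResult:
    """Simulate multi-day dosing and extract each subject's trough.

    The trough is read at ``trough_time_h`` after the first victim dose
    (pre-dose by construction for interval-aligned regimens).  The
    simulated duration must cover the trough time plus one interval.
    """
    t_end = duration_days * 24.0
    if t_end < trough_time_h + victim_regimen.interval_h:
        raise ValueError("simulation shorter than trough time + one interval")
    opts = dict(TRIAL_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    regs = [victim_regimen]
    if perpetrator is not None:
        if interactions is None:
            raise ValueError("perpetrator given without interaction parameters")
        regs.append(perpetrator_regimen)
    rows = []
    for idx, prof in enumerate(design.sample_subjects()):
        profiles = simulate_subject(
            prof, victims, perpetrator, interactions, regs, t_end, opts
        )
        t, c = analyte_concentration(profiles, analyte)
        trough = float(np.interp(trough_time_h + victim_regimen.start_offset_h, t, c))
        rows.append(
            {
                "trial": idx // design.n_subjects_per_trial,
                "subject": prof.subject_id,
                "trough_ng_ml": trough,
            }
        )
    df = pd.DataFrame(rows)
    vals = df["trough_ng_ml"].to_numpy()
    return SafetyResult(
        analyte=analyte,
        trough_time_h=trough_time_h,
        troughs_ng_ml=df,
        median=float(np.median(vals)),
        iqr=(float(np.percentile(vals, 25)), float(np.percentile(vals, 75))),
        thresholds_ng_ml=thresholds_ng_ml
        or {"major_bleeding": 122.1, "any_bleeding": 74.9},
    )


def sensitivity_sweep(
    profile: PhysiologyProfile,
    victims: list[CompoundModel],
    regimens,
    t_end: float,
    perturbations: dict[str, float],
    analytes: list[str] | None = None,
    perpetrator: CompoundModel | None = None,
    interactions: InteractionParameters | None = None,
    auc_window: tuple[float, float] | None = None,
    solver_opts: dict | None = None,
) -> dict[str, float]:
    """Percent AUC change per analyte after scaling abundance parameters.

    ``perturbations`` maps abundance scalar names (e.g. ``CYP3A4``,
    ``PGP_GUT``) to relative changes (-0.255 for a 25.5 % decrease).
    Unknown names raise.  Returns {analyte: (AUC_pert/AUC_base - 1)*100}.
    """
    for key in perturbations:
        if key not in profile.abundance_scalars:
            raise ValueError(f"unknown abundance parameter {key!r}")
    opts = dict(TRIAL_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    window = auc_window or (0.0, t_end)
    base = simulate_subject(
        profile, victims, perpetrator, interactions, regimens, t_end, opts
    )
    perturbed_profile = profile.model_copy(deep=True)
    for key, rel in perturbations.items():
        perturbed_profile.abundance_scalars[key] *= 1.0 + rel
    pert = simulate_subject(
        perturbed_profile, victims, perpetrator, interactions, regimens, t_end, opts
    )
    names = analytes or [v.name for v in victims]
    out = {}
    for name in names:
        a0 = _exposure(base, name, "auc", window)
        a1 = _exposure(pert, name, "auc", window)
        out[name] = (a1 / a0 - 1.0) * 100.0
    return out
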