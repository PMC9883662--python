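"""End-to-end study workflow: verify, interact, extrapolate to older adults.

Ties the modules into the three-step analysis the package exists for:

1. monotherapy exposure per ethnicity and age group (aging effect),
2. paired DDI studies for the victim/perpetrator scenarios, with
   age-normalized interaction ratios,
3. 10-day steady-state trough safety simulations and abundance
   sensitivity sweeps.

Every run is driven by a :class:`RunConfig`, seeded, and emits a
manifest (inputs, seed, package version, stage timings) plus tidy
CSV/JSON outputs, one directory per scenario.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__ as _version
from .compounds import load_bundled_chain, load_bundled_compound, load_interactions
from .metrics import normalize_to_reference
from .population import DemographicSpec, reference_subject
from .trial import (
    Regimen,
    TrialDesign,
    load_scenario,
    run_scenario_study,
    run_steady_state_safety,
    sensitivity_sweep,
)

log = logging.getLogger("pbpkddi.workflow")

AGE_GROUPS: dict[str, tuple[float, float]] = {
    "20-59": (20.0, 59.0),
    "60-74": (60.0, 74.0),
    "75-99": (75.0, 99.0),
}
REFERENCE_GROUP = "20-59"

DDI_SCENARIOS = (
    "dabe_verapamil_staggered",
    "dabe_verapamil_concomitant",
    "dabe_clarithromycin",
    "riva_clarithromycin",
    "riva_fluconazole",
    "riva_ketoconazole",
)
MONO_SCENARIOS = {"dabigatran_etexilate": "dabe_monotherapy", "rivaroxaban": "riva_monotherapy"}

#: maintenance perpetrator regimens for the 10-day safety simulations
SAFETY_PERPETRATOR_REGIMENS = {
    "verapamil": {"dose_mg": 120.0, "interval_h": 12.0},
    "clarithromycin": {"dose_mg": 500.0, "interval_h": 12.0},
}
#: victim dose levels for the safety simulations (standard / reduced)
SAFETY_VICTIM_DOSES = {"standard": 150.0, "reduced_110": 110.0, "reduced_75": 75.0}
BLEEDING_THRESHOLDS_NG_ML = {"major_bleeding": 122.1, "any_bleeding": 74.9}


def make_design(
    ethnicity: str,
    age_group: str,
    n_trials: int = 10,
    n_subjects_per_trial: int = 10,
    seed: int = 0,
) -> TrialDesign:
    lo, hi = AGE_GROUPS[age_group]
    lo = max(lo, 18.0)
    return TrialDesign(
        n_trials=n_trials,
        n_subjects_per_trial=n_subjects_per_trial,
        demographics=DemographicSpec(
            ethnicity=ethnicity, age_min=lo, age_max=hi, n_subjects=1
        ),
        master_seed=seed,
    )


def _group_seed(seed: int, *labels: str) -> int:
    h = hashlib.sha256(("|".join(map(str, labels)) + f"|{seed}").encode()).hexdigest()
    return int(h[:7], 16)


def monotherapy_exposure(
    victim: str,
    ethnicity: str,
    seed: int,
    n_trials: int = 10,
    n_subjects_per_trial: int = 10,
    age_groups=tuple(AGE_GROUPS),
    solver_opts: dict | None = None,
) -> dict[str, float]:
    """Pooled geometric-mean victim AUC per age group (monotherapy)."""
    scenario = load_scenario(MONO_SCENARIOS[victim])
    out = {}
    for group in age_groups:
        design = make_design(
            ethnicity, group, n_trials, n_subjects_per_trial,
            seed=_group_seed(seed, "mono", victim, ethnicity, group),
        )
        res = run_scenario_study(scenario, design, solver_opts=solver_opts)
        out[group] = res.pooled_alone
    return out


def aging_exposure_increase(exposure_by_group: dict[str, float]) -> dict[str, float]:
    """Percent AUC increase of each older group over the adult group."""
    ref = exposure_by_group[REFERENCE_GROUP]
    return {
        g: (v / ref - 1.0) * 100.0
        for g, v in exposure_by_group.items()
        if g != REFERENCE_GROUP
    }


def ddi_ratios_by_group(
    scenario_name: str,
    ethnicity: str,
    seed: int,
    n_trials: int = 10,
    n_subjects_per_trial: int = 10,
    age_groups=tuple(AGE_GROUPS),
    solver_opts: dict | None = None,
) -> dict[str, float]:
    """Pooled DDI AUC ratio per age group for one scenario."""
    scenario = load_scenario(scenario_name)
    out = {}
    for group in age_groups:
        design = make_design(
            ethnicity, group, n_trials, n_subjects_per_trial,
            seed=_group_seed(seed, "ddi", scenario_name, ethnicity, group),
        )
        res = run_scenario_study(scenario, design, solver_opts=solver_opts)
        out[group] = res.pooled_ratio
    return out


def safety_trough_analysis(
    perpetrator: str,
    victim_dose_mg: float,
    ethnicity: str,
    age_group: str,
    seed: int,
    n_trials: int = 10,
    n_subjects_per_trial: int = 10,
    duration_days: float = 10.0,
    solver_opts: dict | None = None,
):
    """10-day concomitant dosing; trough of total dabigatran at 216 h."""
    victims = load_bundled_chain("dabigatran_etexilate")
    perp = load_bundled_compound(perpetrator)
    inter = load_interactions()[perpetrator]
    n_doses = int(duration_days * 24 / 12)
    victim_reg = Regimen(
        compound="dabigatran_etexilate", dose_mg=victim_dose_mg,
        interval_h=12.0, n_doses=n_doses,
    )
    preg = SAFETY_PERPETRATOR_REGIMENS[perpetrator]
    perp_reg = Regimen(
        compound=perpetrator, dose_mg=preg["dose_mg"],
        interval_h=preg["interval_h"],
        n_doses=int(duration_days * 24 / preg["interval_h"]),
    )
    design = make_design(
        ethnicity, age_group, n_trials, n_subjects_per_trial,
        seed=_group_seed(seed, "safety", perpetrator, str(victim_dose_mg),
                         ethnicity, age_group),
    )
    return run_steady_state_safety(
        design, victims, victim_reg, perp, perp_reg, inter,
        duration_days=duration_days,
        thresholds_ng_ml=BLEEDING_THRESHOLDS_NG_ML,
        solver_opts=solver_opts,
    )


def abundance_sensitivity(
    seed: int,
    age: float = 70.0,
    ethnicity: str = "Chinese",
    solver_opts: dict | None = None,
) -> dict[str, float]:
    """AUC change (%) under literature aging-decline abundance scenarios.

    Applies an 8 %-per-decade CYP3A4 decline, accumulated from the adult
    reference age (40 y) whose abundance the base model carries, together
    with a 25.5 % intestinal P-gp decrease (the site the aging expression
    data concern), to a reference older subject; reports victim AUC
    changes in percent.
    """
    del seed  # deterministic reference subject; kept for interface symmetry
    subject = reference_subject(ethnicity=ethnicity, age=age)
    pert = {
        "CYP3A4": -0.08 * (age - 40.0) / 10.0,
        "PGP_GUT": -0.255,
    }
    out: dict[str, float] = {}
    dabe = load_bundled_chain("dabigatran_etexilate")
    res = sensitivity_sweep(
        subject, dabe,
        [Regimen(compound="dabigatran_etexilate", dose_mg=150.0)],
        t_end=96.0, perturbations=pert, analytes=["dabigatran"],
        solver_opts=solver_opts,
    )
    out["dabigatran"] = res["dabigatran"]
    riva = load_bundled_chain("rivaroxaban")
    res = sensitivity_sweep(
        subject, riva,
        [Regimen(compound="rivaroxaban", dose_mg=10.0)],
        t_end=72.0, perturbations=pert, analytes=["rivaroxaban"],
        solver_opts=solver_opts,
    )
    out["rivaroxaban"] = res["rivaroxaban"]
    return out


# ---------------------------------------------------------------------------
# full configured run


class RunConfig(BaseModel):
    """Configuration of a full workflow run."""

    out_dir: str
    seed: int = 0
    ethnicities: list[str] = Field(default_factory=lambda: ["Caucasian", "Chinese"])
    age_groups: list[str] = Field(default_factory=lambda: list(AGE_GROUPS))
    ddi_scenarios: list[str] = Field(default_factory=lambda: list(DDI_SCENARIOS))
    n_trials: int = 10
    n_subjects_per_trial: int = 10
    run_safety: bool = True
    safety_duration_days: float = 10.0
    run_sensitivity: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def run_workflow(config: RunConfig) -> dict:
    """Execute all configured stages; write outputs + manifest; return summary."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = config.model_dump_json(indent=2)
    manifest: dict = {
        "package_version": _version,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": {},
    }
    summary: dict = {}
    kw = dict(
        n_trials=config.n_trials,
        n_subjects_per_trial=config.n_subjects_per_trial,
    )

    def stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s: starting", name)
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"workflow stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 2)}
        log.info("stage %s: done (%.1fs)", name, time.perf_counter() - t0)
        return result

    # 1. monotherapy aging
    def _mono():
        rows = []
        for eth in config.ethnicities:
            for victim in MONO_SCENARIOS:
                expo = monotherapy_exposure(
                    victim, eth, config.seed, age_groups=config.age_groups, **kw
                )
                incr = aging_exposure_increase(expo) if REFERENCE_GROUP in expo else {}
                for g, v in expo.items():
                    rows.append(
                        {
                            "ethnicity": eth,
                            "victim": victim,
                            "age_group": g,
                            "gm_auc_ng_h_ml": v,
                            "increase_vs_adult_pct": incr.get(g, 0.0),
                        }
                    )
        df = pd.DataFrame(rows)
        df.to_csv(out_dir / "monotherapy_aging.csv", index=False)
        return df

    mono_df = stage("monotherapy_aging", _mono)
    summary["monotherapy_aging"] = mono_df.to_dict("records")

    # 2. DDI studies + normalization
    def _ddi():
        rows = []
        for eth in config.ethnicities:
            for name in config.ddi_scenarios:
                ratios = ddi_ratios_by_group(
                    name, eth, config.seed, age_groups=config.age_groups, **kw
                )
                norm = (
                    normalize_to_reference(ratios, REFERENCE_GROUP)
                    if REFERENCE_GROUP in ratios
                    else {}
                )
                for g, r in ratios.items():
                    rows.append(
                        {
                            "ethnicity": eth,
                            "scenario": name,
                            "age_group": g,
                            "ddi_auc_ratio": r,
                            "normalized_ratio": norm.get(g, {}).get(
                                "normalized_ratio", float("nan")
                            ),
                            "within_1_25_fold": norm.get(g, {}).get(
                                "within_1_25_fold", True
                            ),
                        }
                    )
        df = pd.DataFrame(rows)
        df.to_csv(out_dir / "ddi_ratios.csv", index=False)
        return df

    ddi_df = stage("ddi_studies", _ddi)
    summary["ddi_ratios"] = ddi_df.to_dict("records")

    # ratio plots (one per ethnicity: raw ratios, and age-normalized with
    # the 1.25-fold bioequivalence band)
    from .plots import plot_ddi_ratios

    for eth in config.ethnicities:
        sub = ddi_df[ddi_df.ethnicity == eth]
        raw = {
            sc: dict(zip(g.age_group, g.ddi_auc_ratio))
            for sc, g in sub.groupby("scenario")
        }
        if raw:
            plot_ddi_ratios(raw, out_dir / f"ddi_ratios_{eth}.png",
                            title=f"DDI AUC ratio by age group ({eth})")
            norm = {
                sc: dict(zip(g.age_group, g.normalized_ratio))
                for sc, g in sub.groupby("scenario")
            }
            plot_ddi_ratios(
                norm, out_dir / f"ddi_ratios_normalized_{eth}.png",
                reference_band=(1 / 1.25, 1.25),
                title=f"Age-normalized DDI ratio ({eth})",
            )

    # 3. safety troughs
    if config.run_safety:
        def _safety():
            rows = []
            older = [g for g in config.age_groups if g != REFERENCE_GROUP] or list(
                config.age_groups
            )
            for perp in SAFETY_PERPETRATOR_REGIMENS:
                for label, dose in SAFETY_VICTIM_DOSES.items():
                    for g in older:
                        res = safety_trough_analysis(
                            perp, dose, "Chinese", g, config.seed,
                            duration_days=config.safety_duration_days, **kw,
                        )
                        rows.append(
                            {
                                "perpetrator": perp,
                                "dose_label": label,
                                "dose_mg": dose,
                                "age_group": g,
                                "median_trough_ng_ml": res.median,
                                "iqr_low": res.iqr[0],
                                "iqr_high": res.iqr[1],
                                **{
                                    f"exceeds_{k}": v
                                    for k, v in res.exceeds().items()
                                },
                            }
                        )
            df = pd.DataFrame(rows)
            df.to_csv(out_dir / "safety_troughs.csv", index=False)
            return df

        saf_df = stage("steady_state_safety", _safety)
        summary["safety_troughs"] = saf_df.to_dict("records")

    # 4. abundance sensitivity
    if config.run_sensitivity:
        sens = stage("abundance_sensitivity", lambda: abundance_sensitivity(config.seed))
        summary["abundance_sensitivity_pct"] = sens
        (out_dir / "sensitivity.json").write_text(json.dumps(sens, indent=2))

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out_dir / "config.json").write_text(cfg_json)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
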