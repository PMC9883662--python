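import numpy as np
import pandas as pd
import pytest

import pbpkddi as p
from pbpkddi.population import DemographicSpec
from pbpkddi.trial import (
    Regimen,
    TrialDesign,
    load_scenario,
    run_ddi_study,
    run_scenario_study,
    run_steady_state_safety,
    sensitivity_sweep,
    staggered_regimen,
)

from conftest import FAST_OPTS


def small_design(n_trials=1, n_subjects=2, seed=3, ethnicity="Chinese",
                 lo=20.0, hi=59.0):
    return TrialDesign(
        n_trials=n_trials,
        n_subjects_per_trial=n_subjects,
        demographics=DemographicSpec(
            ethnicity=ethnicity, age_min=lo, age_max=hi, n_subjects=1
        ),
        master_seed=seed,
    )


class TestRegimen:
    def test_stagger_zero_is_identity(self):
        base = Regimen(compound="dabigatran_etexilate", dose_mg=150.0)
        assert staggered_regimen(base, 0.0) == base

    def test_stagger_shifts_offset(self):
        base = Regimen(compound="dabigatran_etexilate", dose_mg=150.0,
                       start_offset_h=1.0)
        assert staggered_regimen(base, 2.0).start_offset_h == 3.0

    def test_invalid_regimen_rejected(self):
        with pytest.raises(ValueError):
            Regimen(compound="x", dose_mg=-1.0)
        with pytest.raises(ValueError):
            Regimen(compound="x", dose_mg=1.0, interval_h=0.0)
        with pytest.raises(ValueError):
            staggered_regimen(
                Regimen(compound="x", dose_mg=1.0), -1.0
            )


class TestDDIStudy:
    def test_no_perpetrator_gives_unit_ratio(self, dabe_chain):
        res = run_ddi_study(
            small_design(), dabe_chain,
            Regimen(compound="dabigatran_etexilate", dose_mg=150.0),
            None, None, None, t_end=48.0, analyte="dabigatran",
            solver_opts=FAST_OPTS,
        )
        assert res.pooled_ratio == 1.0
        assert all(res.subjects["ratio"] == 1.0)

    def test_study_is_deterministic(self, dabe_chain, ki_table):
        ver = p.load_bundled_compound("verapamil")
        kw = dict(
            victims=dabe_chain,
            victim_regimen=Regimen(compound="dabigatran_etexilate", dose_mg=150.0),
            perpetrator=ver,
            perpetrator_regimen=Regimen(compound="verapamil", dose_mg=120.0),
            interactions=ki_table["verapamil"],
            t_end=48.0,
            analyte="dabigatran",
            solver_opts=FAST_OPTS,
        )
        a = run_ddi_study(small_design(seed=11), **kw)
        b = run_ddi_study(small_design(seed=11), **kw)
        assert a.pooled_ratio == b.pooled_ratio
        pd.testing.assert_frame_equal(a.subjects, b.subjects)

    def test_pooled_ratio_independent_of_trial_partition(self, dabe_chain,
                                                         ki_table):
        ver = p.load_bundled_compound("verapamil")
        res = run_ddi_study(
            small_design(n_trials=2, n_subjects=3, seed=5), dabe_chain,
            Regimen(compound="dabigatran_etexilate", dose_mg=150.0),
            ver, Regimen(compound="verapamil", dose_mg=120.0),
            ki_table["verapamil"], t_end=48.0, analyte="dabigatran",
            solver_opts=FAST_OPTS,
        )
        ratios = res.subjects["ratio"].to_numpy()
        # pooled geometric mean equals the subject-level geometric mean,
        # however subjects are grouped into trials, and is order-invariant
        assert res.pooled_ratio == pytest.approx(
            float(np.exp(np.mean(np.log(ratios)))), rel=1e-12
        )
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(ratios)
        assert res.pooled_ratio == pytest.approx(
            float(np.exp(np.mean(np.log(shuffled)))), rel=1e-12
        )

    def test_stagger_weakens_interaction(self, ref_caucasian_adult, dabe_chain,
                                         ki_table):
        """2-h separated dosing produces a smaller AUC ratio than
        concomitant dosing for the verapamil single-dose scenario."""
        from pbpkddi.engine import simulate_subject
        from pbpkddi.metrics import auc_trapezoid

        ver = p.load_bundled_compound("verapamil")
        preg = Regimen(compound="verapamil", dose_mg=120.0)
        ratios = {}
        for stagger in (0.0, 2.0):
            vreg = staggered_regimen(
                Regimen(compound="dabigatran_etexilate", dose_mg=150.0), stagger
            )
            alone = simulate_subject(
                ref_caucasian_adult, dabe_chain, None, None, [vreg], 50.0,
                FAST_OPTS,
            )["dabigatran"]
            comb = simulate_subject(
                ref_caucasian_adult, dabe_chain, ver, ki_table["verapamil"],
                [vreg, preg], 50.0, FAST_OPTS,
            )["dabigatran"]
            ratios[stagger] = auc_trapezoid(comb.times, comb.conc_ng_ml) / \
                auc_trapezoid(alone.times, alone.conc_ng_ml)
        assert ratios[2.0] < ratios[0.0]
        assert ratios[2.0] > 1.0

    def test_bundled_scenarios_load(self):
        sc = load_scenario("dabe_verapamil_concomitant")
        assert sc.victim == "dabigatran_etexilate"
        assert sc.perpetrator_reg().dose_mg == 120.0
        with pytest.raises(FileNotFoundError):
            load_scenario("no_such_scenario")

    def test_scenario_study_runs(self, ki_table):
        res = run_scenario_study(
            load_scenario("dabe_verapamil_concomitant"),
            small_design(seed=21),
            solver_opts=FAST_OPTS,
        )
        assert res.pooled_ratio > 1.0
        assert len(res.subjects) == 2


class TestSteadyStateSafety:
    @pytest.mark.parametrize("victim,dose", [
        ("dabigatran_etexilate", 150.0), ("rivaroxaban", 10.0),
    ])
    def test_trough_plateau_reached_by_216h(self, victim, dose, ref_chinese_adult):
        """BID dosing: troughs at 216 h and 228 h differ by < 5%."""
        from pbpkddi.engine import simulate_subject
        from pbpkddi.trial import analyte_concentration

        chain = p.load_bundled_chain(victim)
        reg = Regimen(compound=victim, dose_mg=dose, interval_h=12.0, n_doses=20)
        sim = simulate_subject(
            ref_chinese_adult, chain, None, None, [reg], 240.0, FAST_OPTS
        )
        t, c = analyte_concentration(sim, chain[0].name)
        c216 = float(np.interp(216.0, t, c))
        c228 = float(np.interp(228.0, t, c))
        assert abs(c228 - c216) / c216 < 0.05

    def test_trough_read_at_216h_post_first_dose(self, dabe_chain, ki_table):
        ver = p.load_bundled_compound("verapamil")
        res = run_steady_state_safety(
            small_design(seed=9, lo=60.0, hi=74.0), dabe_chain,
            Regimen(compound="dabigatran_etexilate", dose_mg=150.0,
                    interval_h=12.0, n_doses=20),
            ver,
            Regimen(compound="verapamil", dose_mg=120.0, interval_h=12.0,
                    n_doses=20),
            ki_table["verapamil"],
            solver_opts=FAST_OPTS,
        )
        assert res.trough_time_h == 216.0
        assert set(res.thresholds_ng_ml) == {"major_bleeding", "any_bleeding"}
        assert res.median > 0
        assert res.iqr[0] <= res.median <= res.iqr[1]

    def test_reduced_dose_lowers_trough(self, ref_chinese_adult, dabe_chain):
        from pbpkddi.engine import simulate_subject
        from pbpkddi.trial import analyte_concentration

        troughs = {}
        for dose in (110.0, 150.0):
            reg = Regimen(compound="dabigatran_etexilate", dose_mg=dose,
                          interval_h=12.0, n_doses=20)
            sim = simulate_subject(
                ref_chinese_adult, dabe_chain, None, None, [reg], 240.0,
                FAST_OPTS,
            )
            t, c = analyte_concentration(sim, "total_dabigatran")
            troughs[dose] = float(np.interp(216.0, t, c))
        assert troughs[110.0] < troughs[150.0]

    def test_duration_must_cover_trough(self, dabe_chain):
        with pytest.raises(ValueError, match="shorter"):
            run_steady_state_safety(
                small_design(), dabe_chain,
                Regimen(compound="dabigatran_etexilate", dose_mg=150.0,
                        interval_h=12.0, n_doses=10),
                None, None, None, duration_days=5.0,
            )


class TestSensitivitySweep:
    def test_zero_perturbation_is_zero_change(self, ref_chinese_adult, dabe_chain):
        out = sensitivity_sweep(
            ref_chinese_adult, dabe_chain,
            [Regimen(compound="dabigatran_etexilate", dose_mg=150.0)],
            t_end=72.0, perturbations={"CYP3A4": 0.0},
            analytes=["dabigatran"], solver_opts=FAST_OPTS,
        )
        assert out["dabigatran"] == pytest.approx(0.0, abs=1e-6)

    def test_absent_pathway_is_insensitive(self, ref_chinese_adult, dabe_chain):
        """Dabigatran has no CYP3A4 pathway, so halving CYP3A4 changes
        nothing."""
        out = sensitivity_sweep(
            ref_chinese_adult, dabe_chain,
            [Regimen(compound="dabigatran_etexilate", dose_mg=150.0)],
            t_end=72.0, perturbations={"CYP3A4": -0.5},
            analytes=["dabigatran"], solver_opts=FAST_OPTS,
        )
        assert out["dabigatran"] == pytest.approx(0.0, abs=1e-6)

    def test_cyp3a4_decline_raises_rivaroxaban_exposure(self, ref_chinese_adult,
                                                        riva_chain):
        out = sensitivity_sweep(
            ref_chinese_adult, riva_chain,
            [Regimen(compound="rivaroxaban", dose_mg=10.0)],
            t_end=72.0, perturbations={"CYP3A4": -0.5},
            solver_opts=FAST_OPTS,
        )
        assert out["rivaroxaban"] > 0

    def test_unknown_parameter_rejected(self, ref_chinese_adult, dabe_chain):
        with pytest.raises(ValueError, match="unknown"):
            sensitivity_sweep(
                ref_chinese_adult, dabe_chain,
                [Regimen(compound="dabigatran_etexilate", dose_mg=150.0)],
                t_end=24.0, perturbations={"CYP9Z9": -0.5},
            )
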