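import numpy as np
import pytest

import pbpkddi as p
from pbpkddi.compounds import InteractionParameters
from pbpkddi.engine import (
    hepatic_clearance,
    inhibition_factor,
    pgp_efflux_rate,
    renal_clearance,
    simulate_subject,
)
from pbpkddi.metrics import auc_trapezoid

from conftest import FAST_OPTS, one_compartment_compound


class TestElementaryRates:
    @pytest.mark.parametrize(
        "i_over_ki,expected", [(0.0, 1.0), (1.0, 0.5), (9.0, 0.1)]
    )
    def test_inhibition_factor(self, i_over_ki, expected):
        assert inhibition_factor(i_over_ki * 2.0, 2.0) == pytest.approx(expected)

    def test_inhibition_factor_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            inhibition_factor(1.0, 0.0)
        with pytest.raises(ValueError):
            inhibition_factor(-1.0, 1.0)

    def test_pgp_efflux_limits(self):
        assert pgp_efflux_rate(0.0, 5.0, 10.0) == 0.0
        assert pgp_efflux_rate(5.0, 5.0, 10.0, activity=1.0) == pytest.approx(5.0)
        assert pgp_efflux_rate(5e6, 5.0, 10.0) == pytest.approx(10.0, rel=1e-5)
        with pytest.raises(ValueError):
            pgp_efflux_rate(-1.0, 5.0, 10.0)

    def test_well_stirred_liver(self):
        assert hepatic_clearance(90.0, 1.0, 0.0) == 0.0
        assert hepatic_clearance(90.0, 1.0, 1e12) == pytest.approx(90.0, rel=1e-9)
        assert hepatic_clearance(90.0, 1.0, 10.0) == pytest.approx(9.0)

    def test_renal_clearance(self):
        assert renal_clearance(1.0, 120.0) == pytest.approx(7.2)
        assert renal_clearance(0.0, 120.0, cl_secretion=3.0) == pytest.approx(3.0)
        # full secretion inhibition leaves filtration only
        assert renal_clearance(
            0.5, 100.0, cl_secretion=3.0, secretion_activity=0.0
        ) == pytest.approx(0.5 * 100.0 * 0.06)


class TestSimulateSubject:
    def test_zero_dose_gives_zero_concentrations(self, ref_chinese_adult, dabe_chain):
        reg = p.Regimen(compound="dabigatran_etexilate", dose_mg=0.0)
        res = simulate_subject(
            ref_chinese_adult, dabe_chain, None, None, [reg], 24.0, FAST_OPTS
        )
        for prof in res.values():
            assert np.all(prof.conc_ng_ml == 0.0)

    def test_one_compartment_closed_form(self, ref_chinese_adult, toy_compound):
        """IV-like bolus with linear clearance matches C0*exp(-k t) to 0.1%."""
        reg = p.Regimen(compound="toy", dose_mg=10.0)
        res = simulate_subject(
            ref_chinese_adult, [toy_compound], None, None, [reg], 24.0,
            {"rtol": 1e-10, "atol": 1e-12, "dt": 0.1},
        )["toy"]
        vc = toy_compound.distribution.vc_L_per_kg * ref_chinese_adult.weight
        k = 5.0 / vc
        t = res.times[res.times > 0]
        expected = 10.0 / vc * 1000.0 * np.exp(-k * t)
        sim = res.conc_ng_ml[res.times > 0]
        assert np.max(np.abs(sim - expected) / expected) < 1e-3

    def test_mass_balance_with_perpetrator(self, ref_chinese_adult, dabe_chain,
                                           ki_table):
        ver = p.load_bundled_compound("verapamil")
        regs = [
            p.Regimen(compound="dabigatran_etexilate", dose_mg=150.0,
                      interval_h=12.0, n_doses=3),
            p.Regimen(compound="verapamil", dose_mg=120.0, interval_h=12.0,
                      n_doses=3),
        ]
        res = simulate_subject(
            ref_chinese_adult, dabe_chain, ver, ki_table["verapamil"], regs,
            48.0, FAST_OPTS,
        )
        for prof in res.values():
            assert prof.mass_balance_error() <= 1e-3

    def test_glucuronide_formation_fraction(self, ref_chinese_adult, dabe_chain):
        """~20% of dabigatran elimination is routed to the glucuronide."""
        reg = p.Regimen(compound="dabigatran_etexilate", dose_mg=150.0)
        res = simulate_subject(
            ref_chinese_adult, dabe_chain, None, None, [reg], 120.0, FAST_OPTS
        )
        dab = res["dabigatran"]
        total_elim = sum(v[-1] for v in dab.eliminated_mg.values())
        frac = dab.eliminated_mg["converted"][-1] / total_elim
        assert frac == pytest.approx(0.20, abs=0.02)

    def test_dose_linearity_without_pgp_saturation(self, ref_chinese_adult):
        """With Km pushed far above attained concentrations, AUC scales with
        dose to within 0.5%."""
        chain = p.load_bundled_chain("dabigatran_etexilate")
        chain[0].pgp_gut.km_uM = 1e9
        chain[0].pgp_gut.jmax_mg_h = 150.0 * 1e7  # keep low-conc efflux rate
        aucs = {}
        for dose in (75.0, 300.0):
            reg = p.Regimen(compound="dabigatran_etexilate", dose_mg=dose)
            res = simulate_subject(
                ref_chinese_adult, chain, None, None, [reg], 96.0, FAST_OPTS
            )["dabigatran"]
            aucs[dose] = auc_trapezoid(res.times, res.conc_ng_ml)
        assert aucs[300.0] / aucs[75.0] == pytest.approx(4.0, rel=5e-3)

    def test_ddi_identity_without_ki(self, ref_chinese_adult, dabe_chain):
        """A perpetrator with an empty Ki table leaves the victim unchanged."""
        ver = p.load_bundled_compound("verapamil")
        empty = InteractionParameters(perpetrator="verapamil", ki_uM={})
        vreg = p.Regimen(compound="dabigatran_etexilate", dose_mg=150.0)
        preg = p.Regimen(compound="verapamil", dose_mg=120.0)
        alone = simulate_subject(
            ref_chinese_adult, dabe_chain, None, None, [vreg], 48.0, FAST_OPTS
        )["dabigatran"]
        comb = simulate_subject(
            ref_chinese_adult, dabe_chain, ver, empty, [vreg, preg], 48.0,
            FAST_OPTS,
        )["dabigatran"]
        # identical within (accumulated) solver tolerance
        np.testing.assert_allclose(comb.conc_ng_ml, alone.conc_ng_ml, rtol=1e-4,
                                   atol=1e-6)

    def test_static_limit_auc_ratio(self, ref_chinese_adult):
        """Constant unbound inhibitor, single-pathway low-extraction victim:
        AUC ratio equals 1 + I/Ki within 2%."""
        from pbpkddi.compounds import (
            ClearanceParams, CompoundModel, DistributionParams,
        )

        victim = CompoundModel(
            name="toy_cyp",
            molecular_weight=400.0,
            fu_plasma=0.002,  # keep hepatic extraction very low
            distribution=DistributionParams(vc_L_per_kg=0.5),
            clearance=ClearanceParams(
                clint_L_h={"CYP3A4": 800.0}, renal_filtration=False
            ),
        )
        inter = InteractionParameters(perpetrator="clamp", ki_uM={"CYP3A4": 1.0})
        reg = p.Regimen(compound="toy_cyp", dose_mg=10.0)
        opts = dict(FAST_OPTS, rtol=1e-9, atol=1e-11, dt=0.5)
        base = simulate_subject(
            ref_chinese_adult, [victim], None, inter, [reg], 600.0, opts
        )["toy_cyp"]
        opts["clamp_inhibitor_uM"] = 3.0
        inhib = simulate_subject(
            ref_chinese_adult, [victim], None, inter, [reg], 600.0, opts
        )["toy_cyp"]
        r = auc_trapezoid(inhib.times, inhib.conc_ng_ml) / auc_trapezoid(
            base.times, base.conc_ng_ml
        )
        assert r == pytest.approx(1.0 + 3.0 / 1.0, rel=0.02)

    def test_victim_auc_monotone_in_perpetrator_dose(self, ref_caucasian_adult,
                                                     dabe_chain, ki_table):
        ver = p.load_bundled_compound("verapamil")
        vreg = p.Regimen(compound="dabigatran_etexilate", dose_mg=150.0)
        aucs = []
        for pdose in (0.0, 40.0, 120.0, 360.0):
            regs = [vreg]
            if pdose > 0:
                regs.append(p.Regimen(compound="verapamil", dose_mg=pdose))
            res = simulate_subject(
                ref_caucasian_adult, dabe_chain, ver if pdose > 0 else None,
                ki_table["verapamil"] if pdose > 0 else None, regs, 48.0,
                FAST_OPTS,
            )["dabigatran"]
            aucs.append(auc_trapezoid(res.times, res.conc_ng_ml))
        assert all(b >= a * (1 - 1e-6) for a, b in zip(aucs, aucs[1:]))

    def test_perpetrator_without_interactions_rejected(self, ref_chinese_adult,
                                                       dabe_chain):
        ver = p.load_bundled_compound("verapamil")
        vreg = p.Regimen(compound="dabigatran_etexilate", dose_mg=150.0)
        preg = p.Regimen(compound="verapamil", dose_mg=120.0)
        with pytest.raises(ValueError, match="interaction"):
            simulate_subject(
                ref_chinese_adult, dabe_chain, ver, None, [vreg, preg], 48.0,
                FAST_OPTS,
            )

    def test_t_end_must_cover_doses(self, ref_chinese_adult, toy_compound):
        reg = p.Regimen(compound="toy", dose_mg=1.0, interval_h=24.0, n_doses=4)
        with pytest.raises(ValueError, match="cover"):
            simulate_subject(
                ref_chinese_adult, [toy_compound], None, None, [reg], 48.0,
                FAST_OPTS,
            )
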