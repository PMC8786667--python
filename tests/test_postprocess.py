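"""Envelope application and the post-processing chain: squeezing, splits,
TB carve-out, vaccine adjustment, crisis attribution — all of which must
conserve the envelope total and keep every cause nonnegative."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csmf import CrisisType, MortalityEnvelope, AgeGroup
from csmf.postprocess import (
    allocate_crisis,
    allocate_tb,
    apply_envelope,
    run_postprocessing,
    split_neonatal_sepsis,
    split_perinatal,
    squeeze_exogenous,
    vaccine_adjust,
)


def env(deaths=1000.0, livebirths=100000.0, year=2019):
    return MortalityEnvelope("KEN", year, AgeGroup.CHILD_1TO59M, deaths, livebirths)


class TestApplyEnvelope:
    def test_basic_arithmetic(self):
        d = apply_envelope(np.array([0.5, 0.3, 0.2]), env(1000))
        assert np.allclose(d, [500, 300, 200])

    def test_zero_envelope(self):
        assert np.allclose(apply_envelope(np.array([0.5, 0.5]), env(0.0)), 0.0)

    def test_unnormalised_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            apply_envelope(np.array([0.5, 0.4]), env())


class TestSqueeze:
    def test_stated_rule_arithmetic(self):
        modeled, exo = squeeze_exogenous(1000.0, np.array([0.5, 0.5]),
                                         {"measles": 100.0, "hiv": 50.0})
        assert np.allclose(modeled, [425.0, 425.0])
        assert modeled.sum() + sum(exo.values()) == pytest.approx(1000.0)

    def test_no_exogenous_matches_apply_envelope(self):
        modeled, exo = squeeze_exogenous(1000.0, np.array([0.5, 0.3, 0.2]), {})
        assert np.allclose(modeled, apply_envelope(np.array([0.5, 0.3, 0.2]), env(1000)))
        assert exo == {}

    def test_cap_rescales_pro_rata(self):
        modeled, exo = squeeze_exogenous(
            1000.0, np.array([1.0]), {"measles": 800.0, "hiv": 400.0}, cap_share=0.9
        )
        assert sum(exo.values()) == pytest.approx(900.0)
        assert exo["measles"] / exo["hiv"] == pytest.approx(2.0)
        assert modeled.sum() == pytest.approx(100.0)

    def test_negative_exogenous_rejected(self):
        with pytest.raises(ValueError):
            squeeze_exogenous(1000.0, np.array([1.0]), {"measles": -5.0})


class TestSplits:
    def test_sepsis_meningitis_split(self):
        assert split_neonatal_sepsis(200.0, 0.25) == (150.0, 50.0)
        assert split_neonatal_sepsis(200.0, 0.0) == (200.0, 0.0)
        assert split_neonatal_sepsis(200.0, 1.0) == (0.0, 200.0)

    def test_ratio_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            split_neonatal_sepsis(100.0, 1.2)

    def test_perinatal_split(self):
        assert split_perinatal(100.0, 0.6) == (60.0, 40.0)

    def test_perinatal_default_equal_split_warns(self):
        with pytest.warns(UserWarning, match="equal split"):
            preterm, intrapartum = split_perinatal(100.0)
        assert preterm == intrapartum == 50.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 1e6), st.floats(0, 1))
    def test_conservation(self, deaths, ratio):
        a, b = split_neonatal_sepsis(deaths, ratio)
        assert a >= 0 and b >= 0
        assert a + b == pytest.approx(deaths, rel=1e-12, abs=1e-9)


class TestAllocateTB:
    def test_two_source_rule_with_excess(self):
        lri, other, tb = allocate_tb(500.0, 30.0, 50.0, 40.0)
        assert (lri, other, tb) == (440.0, 0.0, 90.0)

    def test_zero_tb_is_noop(self):
        assert allocate_tb(500.0, 30.0, 0.0, 0.0) == (500.0, 30.0, 0.0)

    def test_truncation_floors_at_zero(self):
        with pytest.warns(UserWarning, match="truncated"):
            lri, other, tb = allocate_tb(50.0, 30.0, 0.0, 100.0)
        assert (lri, other, tb) == (0.0, 0.0, 80.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(*[st.floats(0, 1e4) for _ in range(4)])
    def test_conservation_and_nonnegativity(self, lri, other, tbp, tbe):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lri2, other2, tb = allocate_tb(lri, other, tbp, tbe)
        assert min(lri2, other2, tb) >= 0
        assert lri2 + other2 + tb == pytest.approx(lri + other, rel=1e-9, abs=1e-6)


class TestVaccineAdjust:
    CAUSES = ["lri", "diarrhoea", "other"]

    def test_zero_coverage_is_noop(self):
        d = np.array([1000.0, 500.0, 500.0])
        assert np.allclose(vaccine_adjust(d, self.CAUSES, "lri", 0.0, 0.4), d)

    def test_formula_arithmetic(self):
        d = vaccine_adjust(np.array([1000.0, 0.0, 1000.0]), self.CAUSES, "lri", 0.5, 0.4)
        assert d[0] == pytest.approx(800.0)
        assert d.sum() == pytest.approx(2000.0)  # freed deaths reallocated

    def test_envelope_conserved(self):
        d0 = np.array([700.0, 200.0, 100.0])
        d1 = vaccine_adjust(d0, self.CAUSES, "diarrhoea", 0.8, 0.3, coverage_ref=0.1)
        assert d1.sum() == pytest.approx(d0.sum())
        assert (d1 >= 0).all()

    def test_bad_coverage_rejected(self):
        with pytest.raises(ValueError):
            vaccine_adjust(np.ones(3), self.CAUSES, "lri", 1.5, 0.4)


class TestAllocateCrisis:
    def test_natural_disaster_goes_to_injury(self):
        out = allocate_crisis(1000.0, np.array([0.1, 0.9]), ["injury", "other"],
                              200.0, CrisisType.NATURAL_DISASTER)
        assert np.allclose(out, [280.0, 720.0])

    def test_pro_rata_preserves_distribution(self):
        fr = np.array([0.25, 0.35, 0.4])
        out = allocate_crisis(1000.0, fr, ["a", "b", "c"], 300.0, CrisisType.PRO_RATA)
        assert np.allclose(out / out.sum(), fr)

    def test_zero_crisis_is_noop(self):
        fr = np.array([0.5, 0.5])
        out = allocate_crisis(1000.0, fr, ["injury", "other"], 0.0,
                              CrisisType.NATURAL_DISASTER)
        assert np.allclose(out, 1000.0 * fr)

    def test_crisis_exceeding_envelope_rejected(self):
        with pytest.raises(ValueError):
            allocate_crisis(100.0, np.array([1.0]), ["other"], 200.0, CrisisType.PRO_RATA)


class TestFullChain:
    def test_randomised_conservation(self):
        """The full squeeze->splits->TB->vaccine chain conserves the envelope
        and keeps all causes nonnegative across many random fixtures."""
        rng = np.random.default_rng(77)
        causes = ("lower_respiratory_infections", "diarrhoea", "perinatal", "other")
        for _ in range(300):
            deaths = rng.uniform(100, 1e5)
            raw = rng.dirichlet(np.ones(len(causes)))
            out = run_postprocessing(
                env(deaths),
                raw,
                causes,
                exogenous_deaths={"measles": rng.uniform(0, deaths * 0.3),
                                  "hiv": rng.uniform(0, deaths * 0.2)},
                preterm_share=rng.uniform(0, 1),
                tb_pulmonary=rng.uniform(0, deaths * 0.05),
                tb_extrapulmonary=rng.uniform(0, deaths * 0.05),
                vaccine_adjustments=[
                    ("lower_respiratory_infections", rng.uniform(0, 1), 0.3, 0.0)
                ],
            )
            total = sum(out.values())
            assert abs(total - deaths) / deaths < 1e-6
            assert min(out.values()) >= 0

    def test_deterministic(self):
        causes = ("lower_respiratory_infections", "other")
        kwargs = dict(
            exogenous_deaths={"measles": 50.0}, tb_pulmonary=10.0,
            tb_extrapulmonary=5.0,
        )
        a = run_postprocessing(env(), np.array([0.6, 0.4]), causes, **kwargs)
        b = run_postprocessing(env(), np.array([0.6, 0.4]), causes, **kwargs)
        assert a == b
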