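"""Relative risk, population-weighted RR, attributable mortality, attribution."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from greenozone import (RRModel, attributable_mortality,
                        attribute_to_urban_greening, population_weighted_rr,
                        relative_risk)

from _oracles import health_brute_force

MODEL = RRModel(rr_per_10ppb=1.06, c0=32.4)


class TestRelativeRisk:
    def test_unity_at_threshold(self):
        assert relative_risk(32.4, MODEL) == 1.0
        assert relative_risk(10.0, MODEL) == 1.0

    def test_unit_exponent(self):
        assert relative_risk(42.4, MODEL) == pytest.approx(1.06, rel=1e-12)

    def test_two_increments(self):
        assert relative_risk(52.4, MODEL) == pytest.approx(1.1236, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(-1.0, MODEL)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            RRModel(rr_per_10ppb=0.0)
        with pytest.raises(ValueError):
            RRModel(c0=-1.0)


class TestPopulationWeightedRR:
    def test_all_below_threshold(self):
        assert population_weighted_rr(np.full((3, 3), 20.0),
                                      np.ones((3, 3)), MODEL) == 1.0

    def test_single_populated_cell(self):
        c = np.array([[60.0, 45.0]])
        p = np.array([[0.0, 10.0]])
        assert population_weighted_rr(c, p, MODEL) == pytest.approx(
            relative_risk(45.0, MODEL), rel=1e-14)

    def test_two_cell_hand_value(self):
        c = np.array([42.4, 52.4])
        p = np.array([100.0, 300.0])
        expected = (100 * 1.06 + 300 * 1.06 ** 2) / 400.0   # = 1.1077
        assert population_weighted_rr(c, p, MODEL) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(1.1077, abs=5e-5)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            population_weighted_rr(np.ones(3), np.zeros(3), MODEL)


class TestAttributableMortality:
    def test_zero_below_threshold(self):
        burden = attributable_mortality(np.full((2, 2), 30.0),
                                        np.full((2, 2), 1e4), 0.001, MODEL)
        assert burden.total == 0.0
        assert burden.rr_bar == 1.0

    def test_single_cell_hand_oracle(self):
        rr = 1.06 ** 2                       # C = c0 + 20
        expected = 1000.0 * (0.001 / rr) * (rr - 1.0)
        burden = attributable_mortality(np.array([[52.4]]),
                                        np.array([[1000.0]]), 0.001, MODEL,
                                        season_days=365.0)
        assert burden.total == pytest.approx(expected, rel=1e-10)
        assert burden.total == pytest.approx(0.1100, abs=5e-5)
        assert burden.rr_bar == pytest.approx(rr, rel=1e-12)
        assert burden.i_hat["all"] == pytest.approx(0.001 / rr, rel=1e-12)

    def test_seasonal_scaling_is_linear(self):
        full = attributable_mortality(np.array([[52.4]]), np.array([[1000.0]]),
                                      0.001, MODEL, season_days=365.0)
        jja = attributable_mortality(np.array([[52.4]]), np.array([[1000.0]]),
                                     0.001, MODEL, season_days=92.0)
        assert jja.total == pytest.approx(full.total * 92.0 / 365.0, rel=1e-12)

    def test_uniform_concentration_closed_form(self, rng):
        # with uniform C, RR̄ = RR so M = ΣP·I·(RR−1)/RR exactly
        p = rng.uniform(0, 5000, size=(4, 4))
        c = np.full((4, 4), 58.0)
        rr = relative_risk(58.0, MODEL)
        burden = attributable_mortality(c, p, 0.002, MODEL)
        assert burden.total == pytest.approx(
            p.sum() * 0.002 * (rr - 1.0) / rr, rel=1e-12)

    def test_monotone_in_concentration(self, rng):
        p = rng.uniform(10, 100, size=9)
        c = rng.uniform(20, 80, size=9)
        base = attributable_mortality(c, p, 0.001, MODEL).total
        for i in range(9):
            bumped = c.copy()
            bumped[i] += 5.0
            assert attributable_mortality(bumped, p, 0.001, MODEL).total >= base

    def test_age_groups_additive(self):
        c = np.array([50.0, 60.0])
        p = np.array([1000.0, 2000.0])
        inc = pd.DataFrame({"age_group": ["<65", "65+"],
                            "annual_rate": [0.0002, 0.003]})
        split = attributable_mortality(c, p, inc, MODEL)
        merged = attributable_mortality(c, p, 0.0032, MODEL)
        assert split.total == pytest.approx(merged.total, rel=1e-12)
        assert len(split.by_group) == 2

    def test_negative_incidence_rejected(self):
        with pytest.raises(ValueError):
            attributable_mortality(np.ones(2) * 50, np.ones(2), -0.001, MODEL)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        n = r.integers(1, 100)
        c = r.uniform(0, 90, size=n)
        p = r.uniform(0, 1e5, size=n)
        rates = list(r.uniform(1e-5, 5e-3, size=r.integers(1, 4)))
        rr = r.uniform(1.01, 1.2)
        model = RRModel(rr_per_10ppb=rr, c0=32.4)
        inc = pd.DataFrame({"age_group": [str(i) for i in range(len(rates))],
                            "annual_rate": rates})
        burden = attributable_mortality(c, p, inc, model, season_days=92.0)
        m_exp, grid_exp, rr_bar_exp, i_hat_exp = health_brute_force(
            c, p, rates, rr, 32.4, season_days=92.0)
        assert burden.total == pytest.approx(m_exp, rel=1e-10, abs=1e-12)
        assert burden.rr_bar == pytest.approx(rr_bar_exp, rel=1e-10)
        np.testing.assert_allclose(burden.m_grid.ravel(), grid_exp,
                                   rtol=1e-10, atol=1e-12)


class TestAttribution:
    def test_no_difference_no_attribution(self, rng):
        c = rng.uniform(35, 70, size=(3, 3))
        p = rng.uniform(10, 100, size=(3, 3))
        res = attribute_to_urban_greening(c, c, p, 0.001, MODEL)
        assert res["fraction"] == 0.0
        assert res["attributed"] == 0.0

    def test_all_burden_from_greening(self):
        res = attribute_to_urban_greening(np.array([[32.4]]),
                                          np.array([[50.0]]),
                                          np.array([[1000.0]]), 0.001, MODEL)
        assert res["m_base"] == 0.0
        assert res["fraction"] == 1.0

    def test_fraction_undefined_when_no_burden(self):
        res = attribute_to_urban_greening(np.array([[20.0]]),
                                          np.array([[25.0]]),
                                          np.array([[1000.0]]), 0.001, MODEL)
        assert res["fraction"] is None

    def test_fraction_in_unit_interval(self, rng):
        c_base = rng.uniform(20, 70, size=(4, 4))
        c_ug = c_base + rng.uniform(0, 8, size=(4, 4))
        p = rng.uniform(0, 1e4, size=(4, 4))
        res = attribute_to_urban_greening(c_base, c_ug, p, 0.001, MODEL)
        assert 0.0 <= res["fraction"] <= 1.0
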