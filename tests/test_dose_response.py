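import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import ols_oracle
from uvtox.dose_response import (
    critical_r_squared,
    estimate_ecx,
    fit_effect_dose,
    fit_gamma_loglog,
    fit_potency,
    fit_time_trend,
    select_model,
)
from uvtox.endpoint_processing import EffectPoint, GammaPoint
from uvtox.errors import DegenerateDesignError, DomainError, NoResponseError


def points(concs, effects):
    return [EffectPoint(c, e) for c, e in zip(concs, effects)]


class TestFitEffectDose:
    def test_noiseless_linear_recovery(self):
        concs = [2.5, 5, 10, 20]
        fit = fit_effect_dose(points(concs, [10 + 4 * c for c in concs]),
                              "linear")
        assert fit.intercept == pytest.approx(10.0)
        assert fit.slope == pytest.approx(4.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noiseless_logarithmic_recovery(self):
        concs = [0.5, 1, 2, 4]
        fit = fit_effect_dose(
            points(concs, [50 + 10 * math.log(c) for c in concs]),
            "logarithmic")
        assert fit.intercept == pytest.approx(50.0)
        assert fit.slope == pytest.approx(10.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle_on_noisy_points(self, rng):
        concs = rng.uniform(0.5, 50, size=20)
        effects = 5 + 1.7 * concs + rng.normal(0, 4, size=20)
        fit = fit_effect_dose(points(concs, effects), "linear")
        a, b = ols_oracle(concs, effects)
        assert fit.intercept == pytest.approx(a, abs=1e-10)
        assert fit.slope == pytest.approx(b, abs=1e-10)

    def test_zero_concentration_controls_excluded(self):
        pts = points([0.0, 1.0, 2.0, 4.0], [0.0, 20.0, 30.0, 40.0])
        fit = fit_effect_dose(pts, "logarithmic")
        assert fit.n_points == 3

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_effect_dose(points([5.0, 5.0], [10.0, 20.0]), "linear")

    @given(st.integers(0, 2 ** 31 - 1))
    def test_ols_equivalence_on_random_small_designs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        concs = rng.uniform(0.1, 100, size=n)
        if np.ptp(concs) == 0:  # pragma: no cover
            return
        effects = rng.uniform(-20, 110, size=n)
        for model, x in [("linear", concs), ("logarithmic", np.log(concs))]:
            fit = fit_effect_dose(points(concs, effects), model)
            a, b = ols_oracle(x, effects)
            assert fit.intercept == pytest.approx(a, rel=1e-8, abs=1e-8)
            assert fit.slope == pytest.approx(b, rel=1e-8, abs=1e-8)


class TestEstimateEcx:
    def test_linear_inverse(self):
        fit = fit_effect_dose(points([2, 4, 20], [10, 20, 100]), "linear")
        est = estimate_ecx(fit, 50)
        assert est.value == pytest.approx(10.0)
        assert est.censored == "none"

    def test_logarithmic_inverse(self):
        concs = [0.25, 1, 4]
        fit = fit_effect_dose(
            points(concs, [50 + 10 * math.log(c) for c in concs]),
            "logarithmic")
        assert estimate_ecx(fit, 50).value == pytest.approx(1.0)

    def test_out_of_range_estimate_censored_at_bound(self):
        concs = [10, 50, 100]
        fit = fit_effect_dose(points(concs, [10 + 0.1 * c for c in concs]),
                              "linear")
        est = estimate_ecx(fit, 50, tested_range=(10, 100))
        assert est.censored == "above_max_tested"
        assert est.value == 100  # the violated bound, not the extrapolation
        assert est.extrapolated_value == pytest.approx(400.0)

    def test_zero_slope_is_no_dose_dependence(self):
        fit = fit_effect_dose(points([1, 2, 4], [30, 30, 30]), "linear")
        with pytest.raises(DomainError, match="slope"):
            estimate_ecx(fit, 50)

    def test_inverted_response_flagged(self):
        fit = fit_effect_dose(points([1, 2, 4], [60, 40, 20]), "linear")
        est = estimate_ecx(fit, 50, tested_range=(1, 4))
        assert est.inverted

    @given(k=st.floats(0.01, 1000))
    def test_unit_covariance_of_ec50(self, k):
        concs = np.array([1.0, 2.0, 4.0, 8.0])
        effects = [20.0, 35.0, 60.0, 85.0]
        for model in ("linear", "logarithmic"):
            base = estimate_ecx(fit_effect_dose(points(concs, effects), model))
            scaled = estimate_ecx(
                fit_effect_dose(points(k * concs, effects), model))
            assert scaled.value == pytest.approx(k * base.value, rel=1e-6)


class TestGammaLogLog:
    def test_noiseless_hill_data_recovered_exactly(self):
        pts = [GammaPoint(c, (c / 5.0) ** 2) for c in (1, 2.5, 5, 10)]
        fit, est = fit_gamma_loglog(pts)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert est.value == pytest.approx(5.0, abs=1e-9)

    def test_constant_gamma_has_no_dose_dependence(self):
        with pytest.raises(DomainError, match="slope"):
            fit_gamma_loglog([GammaPoint(c, 1.0) for c in (1, 2, 4)])

    def test_all_zero_gamma_is_no_response(self):
        with pytest.raises(NoResponseError):
            fit_gamma_loglog([GammaPoint(c, 0.0) for c in (1, 2, 4)])

    def test_matches_ols_oracle_in_loglog_space(self, rng):
        concs = rng.uniform(0.5, 20, size=15)
        gammas = (concs / 5.0) ** 1.8 * rng.lognormal(0, 0.2, size=15)
        fit, _ = fit_gamma_loglog(
            [GammaPoint(c, g) for c, g in zip(concs, gammas)])
        a, b = ols_oracle(np.log10(concs), np.log10(gammas))
        assert fit.intercept == pytest.approx(a, abs=1e-10)
        assert fit.slope == pytest.approx(b, abs=1e-10)


class TestCriticalRSquared:
    def test_published_value_at_df_3(self):
        assert round(critical_r_squared(3, 0.05), 2) == 0.77

    def test_df_1_by_hand(self):
        # t(0.975, 1) = 12.706; r2 = t^2/(t^2+1)
        assert round(critical_r_squared(1, 0.05), 2) == 0.99

    def test_decreasing_in_df_and_vanishing(self):
        vals = [critical_r_squared(df) for df in (1, 2, 3, 5, 10, 100, 10000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.001

    def test_increasing_as_alpha_decreases(self):
        assert critical_r_squared(5, 0.01) > critical_r_squared(5, 0.05)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            critical_r_squared(0)
        with pytest.raises(DomainError):
            critical_r_squared(3, alpha=1.5)

    def test_df_convention_switch_in_fits(self):
        pts = points([1, 2, 4], [30.0, 40.0, 52.0])
        standard = fit_effect_dose(pts, "linear", df_convention="standard")
        total = fit_effect_dose(pts, "linear", df_convention="total")
        assert standard.critical_r_squared == pytest.approx(
            critical_r_squared(1))
        assert total.critical_r_squared == pytest.approx(
            critical_r_squared(3))


class TestTimeTrend:
    def test_flat_effects(self):
        fit, direction = fit_time_trend([5, 15, 30], [40, 40, 40])
        assert fit.slope == pytest.approx(0.0)
        assert direction == "flat"

    def test_increasing_trend_with_known_slope(self):
        fit, direction = fit_time_trend([5, 15, 30], [30, 40, 50])
        assert direction == "increasing"
        assert fit.slope == pytest.approx(250 / 316.6667, abs=1e-4)  # 0.7895

    def test_exact_line_is_significant_under_both_conventions(self):
        for convention in ("standard", "total"):
            fit, _ = fit_time_trend([5, 15, 30], [10, 30, 60],
                                    df_convention=convention)
            assert fit.r_squared <= 1.0
        fit, _ = fit_time_trend([5, 15, 30], [10, 20, 35])
        # noisy line: R2 < 1 but still computed against the critical value
        assert 0 <= fit.r_squared <= 1

    def test_perfect_line_r2_is_one(self):
        fit, _ = fit_time_trend([5, 15, 30], [5.0, 15.0, 30.0])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.significant

    def test_degenerate_single_time(self):
        with pytest.raises(DegenerateDesignError):
            fit_time_trend([15, 15], [40, 50])


class TestSelectModel:
    def test_higher_r_squared_wins(self):
        concs = [1, 2, 4, 8]
        # exactly log-linear: logarithmic fit dominates
        pts = points(concs, [50 + 12 * math.log(c) for c in concs])
        lin = fit_effect_dose(pts, "linear")
        log = fit_effect_dose(pts, "logarithmic")
        assert select_model(lin, log) is log

    def test_tie_breaks_toward_linear(self):
        concs = [1, 2]  # two points: both models are exact
        pts = points(concs, [20.0, 40.0])
        lin = fit_effect_dose(pts, "linear")
        log = fit_effect_dose(pts, "logarithmic")
        assert select_model(lin, log) is lin

    def test_degenerate_fit_falls_back_to_the_other(self):
        pts = points([1, 2, 4], [10, 20, 40])
        lin = fit_effect_dose(pts, "linear")
        assert select_model(lin, None) is lin
        assert select_model(None, lin) is lin
        with pytest.raises(DomainError):
            select_model(None, None)


class TestFitPotency:
    def test_pipeline_recovers_noiseless_log_model(self):
        concs = [0.5, 1, 2, 4, 8]
        pts = points(concs, [50 + 15 * math.log(c) for c in concs])
        est = fit_potency(pts, compound="X", organism="daphnia_magna")
        assert est.value == pytest.approx(1.0, abs=1e-9)
        assert est.fit.model == "logarithmic"
        assert est.compound == "X"
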