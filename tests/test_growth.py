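import numpy as np
import pytest

from canemetrics.errors import DomainError, InputError
from canemetrics.growth import (
    fit_logistic,
    fit_trend,
    growth_stage,
    logistic,
    refit_constrained,
    widen_ci,
)


class TestFitLogistic:
    def test_exact_recovery_on_noise_free_data(self, clean_logistic_data):
        t, y = clean_logistic_data
        p = fit_logistic(t, y)
        assert p.delta_y == pytest.approx(2.5, rel=1e-6)
        assert p.k == pytest.approx(0.03, rel=1e-6)
        assert p.t0 == pytest.approx(150.0, rel=1e-6)
        assert p.rmse < 1e-9

    def test_midpoint_identity(self, clean_logistic_data):
        t, y = clean_logistic_data
        p = fit_logistic(t, y)
        assert p(p.t0) == pytest.approx(p.delta_y / 2.0, rel=1e-12)

    def test_declining_curve_negative_rate(self):
        t = np.linspace(20, 400, 12)
        y = logistic(t, 14.0, -0.009, 455.0)
        p = fit_logistic(t, y)
        np.testing.assert_allclose(p(t), y, rtol=1e-8)
        assert p.k < 0

    def test_monotone_and_bounded_for_positive_rate(self, clean_logistic_data):
        t, y = clean_logistic_data
        p = fit_logistic(t, y)
        grid = np.linspace(0, 500, 200)
        vals = p(grid)
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals > 0) and np.all(vals < p.delta_y)

    def test_noisy_recovery_rate(self):
        """Delta_y recovered within 10% in at least 90 of 100 noisy fits."""
        rng = np.random.default_rng(11)
        t = np.linspace(10, 400, 40)
        truth = logistic(t, 2.5, 0.03, 150.0)
        hits = 0
        for _ in range(100):
            y = truth + 0.25 * rng.standard_normal(t.size)
            p = fit_logistic(t, y)
            hits += abs(p.delta_y - 2.5) / 2.5 < 0.10
        assert hits >= 90

    def test_origin_forcing_pulls_curve_toward_zero(self):
        t = np.linspace(40, 360, 10)
        y = logistic(t, 2.5, 0.015, 120.0)  # f(0) = 0.35, far from zero
        free = fit_logistic(t, y)
        forced = fit_logistic(t, y, force_origin=True, origin_weight=5.0)
        assert abs(forced(0.0)) < abs(free(0.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            fit_logistic([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])

    def test_negative_days_rejected(self):
        with pytest.raises(DomainError):
            fit_logistic([-1.0, 2.0, 3.0, 4.0], [0.1, 0.2, 0.3, 0.4])

    def test_confidence_intervals_bracket_estimates(self):
        rng = np.random.default_rng(3)
        t = np.linspace(10, 400, 30)
        y = logistic(t, 2.5, 0.03, 150.0) + 0.1 * rng.standard_normal(30)
        p = fit_logistic(t, y)
        for est, (lo, hi) in zip(p.coefficients, p.ci95):
            assert lo <= est <= hi


class TestRefitConstrained:
    def test_self_consistency_on_pooled_data(self, clean_logistic_data):
        t, y = clean_logistic_data
        rng = np.random.default_rng(5)
        yn = y + 0.05 * rng.standard_normal(y.size)
        general = fit_logistic(t, yn)
        again = refit_constrained(general, t, yn)
        np.testing.assert_allclose(again.coefficients, general.coefficients,
                                   rtol=1e-6)

    @pytest.mark.parametrize("seed", range(25))
    def test_output_always_inside_widened_bounds(self, seed):
        """Hard contract: re-fitted coefficients lie in the widened box."""
        rng = np.random.default_rng(seed)
        dy = rng.uniform(1.5, 3.5)
        k = rng.uniform(0.01, 0.04)
        t0 = rng.uniform(100, 220)
        t = np.sort(rng.uniform(10, 400, 25))
        y = logistic(t, dy, k, t0) + rng.uniform(0.05, 0.3) * rng.standard_normal(25)
        general = fit_logistic(t, y)
        sub = rng.choice(25, size=10, replace=False)
        refit = refit_constrained(general, t[sub], y[sub])
        bounds = widen_ci(general.ci95, 0.10)
        lo0 = max(bounds[0][0], 1e-12)
        assert lo0 <= refit.delta_y <= bounds[0][1] + 1e-9
        for i in (1, 2):
            assert bounds[i][0] - 1e-9 <= refit.coefficients[i] <= bounds[i][1] + 1e-9

    def test_two_population_refits_pull_toward_field_truths(self):
        rng = np.random.default_rng(17)
        t = np.linspace(15, 400, 30)
        y_a = logistic(t, 2.2, 0.03, 150.0) + 0.05 * rng.standard_normal(30)
        y_b = logistic(t, 2.8, 0.03, 150.0) + 0.05 * rng.standard_normal(30)
        general = fit_logistic(np.concatenate([t, t]), np.concatenate([y_a, y_b]))
        assert general.delta_y == pytest.approx(2.5, abs=0.15)
        fit_a = refit_constrained(general, t, y_a)
        fit_b = refit_constrained(general, t, y_b)
        assert fit_a.delta_y < general.delta_y < fit_b.delta_y

    def test_halfwidth_vs_relative_expansion_modes(self):
        ci = ((1.0, 2.0), (-0.5, 0.5), (100.0, 200.0))
        hw = widen_ci(ci, 0.10, "halfwidth")
        assert hw[0] == pytest.approx((0.95, 2.05))
        rel = widen_ci(ci, 0.10, "relative")
        assert rel[0] == pytest.approx((0.9, 2.2))

    def test_infinite_general_ci_rejected(self):
        ci = ((1.0, float("inf")), (0.0, 1.0), (0.0, 1.0))
        with pytest.raises(InputError):
            widen_ci(ci)


class TestFitTrend:
    def test_through_origin_line(self):
        fit = fit_trend([1.0, 2.0], [2.0, 4.0], "linear_through_origin")
        assert fit.coefficients[0] == pytest.approx(2.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_through_origin_exact_recovery(self):
        t = np.linspace(10, 400, 12)
        y = 0.002 * t + 1e-5 * t**2
        fit = fit_trend(t, y, "poly2_through_origin")
        np.testing.assert_allclose(fit.coefficients, [0.002, 1e-5], rtol=1e-9)

    def test_linear_fit_has_intercept(self):
        t = np.array([0.0, 100.0, 200.0, 300.0])
        fit = fit_trend(t, 850.0 + 0.7 * t, "linear")
        np.testing.assert_allclose(fit.coefficients, [850.0, 0.7], rtol=1e-9)

    def test_rmse_estimates_noise_scale(self):
        """The trend RMSE is the function-fitting sigma of the quantity."""
        rng = np.random.default_rng(23)
        t = np.linspace(20, 400, 30)
        y = 850.0 + 0.7 * t + 65.0 * rng.standard_normal(30)
        fit = fit_trend(t, y, "linear")
        assert fit.rmse == pytest.approx(65.0, rel=0.20)

    def test_rank_deficiency_and_size_errors(self):
        from canemetrics.errors import FitError

        with pytest.raises(FitError):
            fit_trend([5.0, 5.0, 5.0], [1.0, 2.0, 3.0], "linear")
        with pytest.raises(InputError):
            fit_trend([1.0], [1.0], "poly2_through_origin")
        with pytest.raises(InputError):
            fit_trend([1.0, 2.0], [1.0, 2.0], "cubic")


class TestGrowthStage:
    @pytest.mark.parametrize("t,stage", [
        (0, "early"), (100, "early"), (149, "early"),
        (150, "mid"), (225, "mid"), (300, "mid"),
        (301, "late"), (400, "late"),
    ])
    def test_boundaries(self, t, stage):
        assert growth_stage(t) == stage

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            growth_stage(-1)
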