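import numpy as np
import pytest
from scipy.interpolate import make_smoothing_spline

from msdrift import (
    EstimationError,
    ParameterError,
    TrendSpec,
    constant_trend,
    linear_trend,
    loess_trend,
    moving_median_trend,
    polynomial_trend,
    spline_trend,
)
from msdrift.trends import GCV_LAMBDA_GRID, fit_trend


class TestTrendSpec:
    def test_parameter_must_match_method(self):
        from msdrift import ConfigurationError

        with pytest.raises(ConfigurationError):
            TrendSpec(method="loess")  # alpha missing
        with pytest.raises(ConfigurationError):
            TrendSpec(method="linear", w=3)  # w does not belong to linear

    def test_spline_lambda_defaults_to_auto(self):
        assert TrendSpec(method="spline").lam == "auto"

    def test_mapping_round_trip(self):
        spec = TrendSpec(method="loess", alpha=0.45, scope="qc_only", application="global")
        assert TrendSpec.from_mapping(spec.to_mapping()) == spec


class TestConstant:
    def test_mean(self):
        fit = constant_trend([1, 2, 3], [2, 4, 6], "mean")
        np.testing.assert_array_equal(fit.factors, [4, 4, 4])

    def test_median_robust(self):
        fit = constant_trend([1, 2, 3], [1, 1, 100], "median")
        np.testing.assert_array_equal(fit.factors, [1, 1, 1])

    def test_mean_matches_sum_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 10, 25)
        fit = constant_trend(np.arange(1, 26), v, "mean")
        total = 0.0
        for x in v:
            total += x
        assert fit.factors[0] == pytest.approx(total / 25, rel=1e-12)

    def test_empty_is_estimation_error(self):
        with pytest.raises(EstimationError):
            constant_trend([], [], "mean")


class TestLinear:
    def test_exact_line(self):
        i = np.arange(1, 8, dtype=float)
        fit = linear_trend(i, 2 * i + 1, eval_ranks=np.arange(1, 11, dtype=float))
        np.testing.assert_allclose(fit.factors, 2 * np.arange(1, 11) + 1, rtol=1e-12)

    def test_constant_values_zero_slope(self):
        fit = linear_trend([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.diagnostics["slope"] == pytest.approx(0, abs=1e-12)
        np.testing.assert_allclose(fit.factors, 5)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        x = np.arange(1.0, 21.0)
        y = rng.normal(50, 10, 20)
        fit = linear_trend(x, y)
        # closed-form normal equations
        sx, sy, sxx, sxy, n = x.sum(), y.sum(), (x * x).sum(), (x * y).sum(), 20
        beta = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        alpha = (sy - beta * sx) / n
        assert fit.diagnostics["slope"] == pytest.approx(beta, rel=1e-10)
        assert fit.diagnostics["intercept"] == pytest.approx(alpha, rel=1e-10)

    def test_single_rank_is_estimation_error(self):
        with pytest.raises(EstimationError):
            linear_trend([3, 3], [1, 2])


class TestMovingMedian:
    def test_constant_series_any_width(self):
        for w in (0, 1, 3, 10):
            fit = moving_median_trend(np.arange(1, 9), np.full(8, 7.0), w)
            np.testing.assert_array_equal(fit.factors, 7.0)

    def test_full_window_equals_global_median(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 5, 9)
        fit = moving_median_trend(np.arange(1, 10), v, w=20)
        np.testing.assert_allclose(fit.factors, np.median(v))

    def test_zero_width_reproduces_values(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0, 5, 12)
        fit = moving_median_trend(np.arange(1, 13), v, w=0)
        np.testing.assert_array_equal(fit.factors, v)

    @pytest.mark.parametrize("w", [1, 2, 3, 4, 5])
    def test_matches_exhaustive_window_scan(self, w):
        rng = np.random.default_rng(w)
        ranks = np.arange(1, 31, dtype=float)
        v = rng.uniform(0, 100, 30)
        fit = moving_median_trend(ranks, v, w)
        for i, r in enumerate(ranks):
            window = [v[j] for j in range(30) if abs(ranks[j] - r) <= w]
            assert fit.factors[i] == np.median(window)

    def test_interpolation_at_non_fit_ranks(self):
        fit = moving_median_trend([2, 4], [10.0, 20.0], w=0,
                                  eval_ranks=[1, 2, 3, 4, 5])
        np.testing.assert_array_equal(fit.factors, [10, 10, 15, 20, 20])

    def test_negative_width_rejected(self):
        with pytest.raises(ParameterError):
            moving_median_trend([1, 2], [1, 2], w=-1)


class TestPolynomial:
    def test_degree_one_equals_linear(self):
        rng = np.random.default_rng(4)
        x = np.arange(1.0, 16.0)
        y = rng.uniform(10, 20, 15)
        pf = polynomial_trend(x, y, 1)
        lf = linear_trend(x, y)
        np.testing.assert_allclose(pf.factors, lf.factors, rtol=1e-9)

    def test_exact_quadratic_recovery(self):
        x = np.arange(1.0, 10.0)
        fit = polynomial_trend(x, x**2, 2, eval_ranks=np.arange(1.0, 13.0))
        np.testing.assert_allclose(fit.factors, np.arange(1.0, 13.0) ** 2, rtol=1e-10)

    def test_matches_least_squares_oracle_and_local_optimality(self):
        rng = np.random.default_rng(5)
        x = np.arange(1.0, 61.0)
        y = np.sin(x / 10) * 20 + rng.normal(0, 2, 60)
        fit = polynomial_trend(x, y, 6)
        # generic least-squares oracle on the scaled design
        z = (2 * x - (x.min() + x.max())) / (x.max() - x.min())
        V = np.vander(z, 7, increasing=True)
        coef, *_ = np.linalg.lstsq(V, y, rcond=None)
        np.testing.assert_allclose(fit.factors, V @ coef, rtol=1e-8)
        # perturbing coefficients never lowers the residual sum of squares
        rss = ((y - V @ coef) ** 2).sum()
        rng2 = np.random.default_rng(6)
        for _ in range(20):
            pert = coef + rng2.normal(0, 1e-3, 7)
            assert ((y - V @ pert) ** 2).sum() >= rss

    def test_underdetermined_is_estimation_error(self):
        with pytest.raises(EstimationError):
            polynomial_trend([1, 2, 3], [1, 2, 3], 3)


class TestSpline:
    def test_matches_scipy_at_fixed_lambda(self):
        rng = np.random.default_rng(7)
        x = np.arange(1.0, 26.0)
        y = np.cos(x / 4) + rng.normal(0, 0.3, 25)
        for lam in (0.01, 1.0, 100.0):
            ours = spline_trend(x, y, lam=lam).factors
            oracle = make_smoothing_spline(x, y, lam=lam)(x)
            np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_infinite_smoothing_limit_is_linear(self):
        rng = np.random.default_rng(8)
        x = np.arange(1.0, 31.0)
        y = rng.uniform(100, 200, 30)
        lin = linear_trend(x, y).factors
        dev_prev = np.inf
        for lam in (1e4, 1e6, 1e9 * np.ptp(y)):
            dev = np.max(np.abs(spline_trend(x, y, lam=lam).factors - lin))
            assert dev <= dev_prev + 1e-12
            dev_prev = dev
        assert dev_prev < 1e-3 * np.ptp(y)

    def test_zero_smoothing_limit_interpolates(self):
        rng = np.random.default_rng(9)
        x = np.arange(1.0, 13.0)
        y = rng.uniform(0, 10, 12)
        fit = spline_trend(x, y, lam=1e-10)
        np.testing.assert_allclose(fit.factors, y, atol=1e-6)

    def test_auto_lambda_attains_grid_gcv_minimum(self):
        """GCV-chosen penalty matches an exhaustive, scipy-based grid oracle."""
        rng = np.random.default_rng(10)
        x = np.arange(1.0, 41.0)
        y = np.sin(x / 5) * 10 + rng.normal(0, 1.5, 40)
        fit = spline_trend(x, y, lam="auto")
        m = len(x)
        scores = []
        for lam in GCV_LAMBDA_GRID:
            S = np.column_stack(
                [make_smoothing_spline(x, col, lam=lam)(x) for col in np.eye(m)]
            )
            resid = y - S @ y
            scores.append(m * (resid @ resid) / (m - np.trace(S)) ** 2)
        assert fit.diagnostics["lam"] == pytest.approx(
            GCV_LAMBDA_GRID[int(np.argmin(scores))]
        )

    def test_too_few_points_is_estimation_error(self):
        with pytest.raises(EstimationError):
            spline_trend([1, 2, 3], [1, 2, 3], lam=1.0)


class TestLoess:
    def test_constant_series(self):
        for alpha in (0.3, 0.7, 1.0):
            fit = loess_trend(np.arange(1, 11), np.full(10, 3.5), alpha)
            np.testing.assert_allclose(fit.factors, 3.5)

    def test_reproduces_straight_line(self):
        x = np.arange(1.0, 21.0)
        y = 3 * x - 7
        for alpha in (0.3, 0.6, 1.0):
            fit = loess_trend(x, y, alpha, eval_ranks=np.arange(1.0, 26.0))
            np.testing.assert_allclose(fit.factors, 3 * np.arange(1.0, 26.0) - 7, rtol=1e-9)

    def test_matches_per_point_wls_oracle(self):
        rng = np.random.default_rng(11)
        x = np.arange(1.0, 31.0)
        y = rng.uniform(0, 50, 30)
        alpha = 0.5
        fit = loess_trend(x, y, alpha)
        q = int(np.ceil(alpha * 30))
        for k, x0 in enumerate(x):
            d = np.abs(x - x0)
            d_q = np.sort(d)[q - 1]
            wts = np.clip(1 - (d / d_q) ** 3, 0, None) ** 3
            X = np.column_stack([np.ones(30), x - x0])
            W = np.diag(wts)
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
            assert fit.factors[k] == pytest.approx(beta[0], rel=1e-8)

    def test_tiny_neighbourhood_rejected(self):
        with pytest.raises(ParameterError):
            loess_trend(np.arange(1, 31), np.ones(30), alpha=0.03)


SPECS = [
    TrendSpec(method="constant", averaging="median"),
    TrendSpec(method="linear"),
    TrendSpec(method="moving_median", w=2),
    TrendSpec(method="polynomial", n=3),
    TrendSpec(method="spline", lam=10.0),
    TrendSpec(method="spline"),  # auto lambda
    TrendSpec(method="loess", alpha=0.5),
]


@pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.label())
class TestSharedInvariants:
    x = np.arange(1.0, 25.0)

    def _values(self):
        rng = np.random.default_rng(99)
        return rng.uniform(10, 30, 24)

    def test_shift_equivariance(self, spec):
        y = self._values()
        base = fit_trend(spec, self.x, y).factors
        shifted = fit_trend(spec, self.x, y + 13.5).factors
        np.testing.assert_allclose(shifted, base + 13.5, rtol=1e-8, atol=1e-8)

    def test_scale_equivariance(self, spec):
        y = self._values()
        base = fit_trend(spec, self.x, y).factors
        scaled = fit_trend(spec, self.x, y * 4.25).factors
        np.testing.assert_allclose(scaled, base * 4.25, rtol=1e-8)

    def test_finite_beyond_fit_span(self, spec):
        """Extrapolation contract: factors finite at ranks outside the fit span."""
        fit_ranks = np.arange(5.0, 20.0)
        y = self._values()[:15]
        eval_ranks = np.arange(1.0, 29.0)
        fit = fit_trend(spec, fit_ranks, y, eval_ranks)
        assert np.all(np.isfinite(fit.factors))
        assert len(fit.factors) == len(eval_ranks)
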