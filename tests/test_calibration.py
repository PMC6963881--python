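"""Calibration regression: OLS/WLS coefficients, F-test, %RE selection, LOD/LOQ."""

import numpy as np
import pytest
from scipy import stats

from chromaval.calibration import (
    WEIGHT_SCHEMES,
    CalibrationSeries,
    RegressionFit,
    calibrate,
    detection_limits,
    f_test_homoscedasticity,
    fit_ols,
    fit_weighted,
    residuals,
    select_best_scheme,
)
from chromaval.errors import (
    FitUndefinedError,
    InputMismatchError,
    LimitsUndefinedError,
    NoDataError,
    WeightUndefinedError,
)
from chromaval.errors import TestUndefinedError as VarianceTestUndefined


def _series_on_line(slope, intercept, reps=3):
    conc = np.array([0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    y = slope * conc + intercept
    return CalibrationSeries(conc, np.tile(y[:, None], (1, reps)))


class TestSeriesContainer:
    def test_from_points_groups_replicates(self):
        s = CalibrationSeries.from_points([1, 2, 1, 2], [10, 20, 11, 21])
        assert s.n_levels == 2 and s.n_replicates == 2
        assert s.x.tolist() == [1, 1, 2, 2]

    def test_ragged_rejected(self):
        with pytest.raises(InputMismatchError):
            CalibrationSeries.from_points([1, 1, 2], [10, 11, 20])

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(FitUndefinedError):
            CalibrationSeries(np.array([0.0, 1.0, 2.0]), np.ones((3, 2)))


class TestExactLine:
    def test_positive_slope(self, exact_line_series):
        fit = fit_ols(exact_line_series)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0, abs=1e-12)
        assert fit.s_y == pytest.approx(0.0, abs=1e-9)

    def test_negative_slope_sign_convention(self):
        fit = fit_ols(_series_on_line(-3.0, 5.0))
        assert fit.slope == pytest.approx(-3.0, abs=1e-12)
        assert fit.r == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("scheme", WEIGHT_SCHEMES)
    def test_every_scheme_reproduces_the_line(self, exact_line_series, scheme):
        fit = fit_weighted(exact_line_series, scheme)
        assert fit.slope == pytest.approx(2.0, rel=1e-10)
        assert fit.intercept == pytest.approx(1.0, rel=1e-8)
        assert abs(fit.r) == pytest.approx(1.0, abs=1e-10)
        assert fit.sum_abs_re == pytest.approx(0.0, abs=1e-6)


class TestAgainstIndependentFits:
    def test_unit_weights_match_scipy_linregress(self, noisy_series):
        fit = fit_ols(noisy_series)
        ref = stats.linregress(noisy_series.x, noisy_series.y)
        assert fit.slope == pytest.approx(ref.slope, rel=1e-12)
        assert fit.intercept == pytest.approx(ref.intercept, rel=1e-12)
        assert fit.r == pytest.approx(ref.rvalue, rel=1e-12)

    @pytest.mark.parametrize("scheme", WEIGHT_SCHEMES[1:])
    def test_weighted_coefficients_match_statsmodels(self, noisy_series, scheme):
        sm = pytest.importorskip("statsmodels.api")
        fit = fit_weighted(noisy_series, scheme)
        X = sm.add_constant(noisy_series.x)
        res = sm.WLS(noisy_series.y, X, weights=fit.weights).fit()
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-9)
        assert fit.slope == pytest.approx(res.params[1], rel=1e-9)

    @pytest.mark.parametrize("scheme", ["1", "1/y", "1/x^2"])
    def test_normal_equations_match_brute_force_minimizer(self, scheme):
        # 5-point instance; oracle = direct numerical minimization of the
        # weighted SSE, independent of the closed-form solution
        from scipy.optimize import minimize

        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.3])
        series = CalibrationSeries(x, y[:, None])
        fit = fit_weighted(series, scheme)
        w = fit.weights

        def sse(p):
            return float(np.sum(w * (y - p[0] * x - p[1]) ** 2))

        res = minimize(sse, x0=[1.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 10000})
        assert fit.slope == pytest.approx(res.x[0], abs=1e-6)
        assert fit.intercept == pytest.approx(res.x[1], abs=1e-6)


class TestResiduals:
    def test_exact_line_residuals_vanish(self, exact_line_series):
        fit = fit_ols(exact_line_series)
        assert np.allclose(residuals(exact_line_series, fit), 0.0, atol=1e-9)

    def test_unweighted_residuals_sum_to_zero(self, noisy_series):
        fit = fit_ols(noisy_series)
        assert abs(residuals(noisy_series, fit).sum()) < 1e-6 * abs(noisy_series.y).max()

    def test_perturbed_point_residual_matches_hat_matrix(self):
        # y = x with one point perturbed by +delta: the residual at that point
        # is delta*(1 - h_ii) with h from the hat matrix computed directly
        x = np.array([1.0, 2.0, 3.0, 4.0])
        delta = 0.5
        y = x.copy()
        y[2] += delta
        series = CalibrationSeries(x, y[:, None])
        fit = fit_ols(series)
        X = np.column_stack([np.ones_like(x), x])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        assert residuals(series, fit)[2] == pytest.approx(delta * (1 - H[2, 2]), rel=1e-9)

    def test_mismatched_fit_rejected(self, exact_line_series):
        five = CalibrationSeries(np.array([1.0, 2, 3, 4, 5]), np.arange(5.0)[:, None] + 1)
        with pytest.raises(InputMismatchError):
            residuals(five, fit_ols(exact_line_series))


class TestHomoscedasticityFTest:
    def test_triplicate_critical_value_is_99(self):
        conc = np.array([0.5, 4.0, 7.0])
        resp = np.array([[10.0, 10.1, 9.9], [50, 51, 49], [70.0, 72.0, 68.0]])
        res = f_test_homoscedasticity(CalibrationSeries(conc, resp), confidence=0.99)
        assert res.f_crit == pytest.approx(99.0, abs=0.5)
        assert res.df == (2, 2)

    def test_equal_variances_give_f_one(self):
        conc = np.array([1.0, 2.0, 3.0])
        resp = np.array([[9.0, 10.0, 11.0], [19, 20, 21], [29.0, 30.0, 31.0]])
        res = f_test_homoscedasticity(CalibrationSeries(conc, resp))
        assert res.f_calc == pytest.approx(1.0)
        assert not res.heteroscedastic

    def test_large_ratio_flags_heteroscedastic(self):
        # top-level variance 228x the bottom one
        lo = np.array([10.0, 10.5, 11.0])  # var 0.25
        hi_sd = np.sqrt(228 * np.var(lo, ddof=1))
        hi = np.array([100.0 - hi_sd, 100.0, 100.0 + hi_sd])  # var = 228*0.25
        conc = np.array([1.0, 2.0, 3.0])
        resp = np.vstack([lo, (lo + hi) / 2, hi])
        res = f_test_homoscedasticity(CalibrationSeries(conc, resp))
        assert res.f_calc == pytest.approx(228.0, rel=1e-9)
        assert res.heteroscedastic

    def test_swapped_extremes_same_f(self):
        conc = np.array([1.0, 2.0, 3.0])
        lo = np.array([9.0, 10.0, 11.0])
        hi = np.array([25.0, 30.0, 35.0])
        a = f_test_homoscedasticity(CalibrationSeries(conc, np.vstack([lo, lo, hi])))
        b = f_test_homoscedasticity(CalibrationSeries(conc, np.vstack([hi, lo, lo])))
        assert a.f_calc == pytest.approx(b.f_calc)
        assert a.f_calc >= 1.0

    def test_undefined_cases(self):
        conc = np.array([1.0, 2.0, 3.0])
        flat = np.array([[10.0, 10.0, 10.0], [20, 21, 19], [30.0, 31.0, 29.0]])
        with pytest.raises(VarianceTestUndefined):
            f_test_homoscedasticity(CalibrationSeries(conc, flat))
        single = CalibrationSeries(conc, np.array([[10.0], [20.0], [30.0]]))
        with pytest.raises(VarianceTestUndefined):
            f_test_homoscedasticity(single)


def _dummy_fit(scheme, sum_abs_re, r=0.99):
    return RegressionFit(scheme=scheme, slope=1.0, intercept=0.0, r=r, s_y=0.1,
                         sd_slope=0.01, sd_intercept=0.01,
                         pct_re=np.zeros(1), sum_abs_re=sum_abs_re, n_points=5)


class TestSchemeSelection:
    def test_published_sums_select_one_over_y(self):
        sums = {"1": 147, "1/y^0.5": 55, "1/y": 2, "1/y^2": 12,
                "1/x^0.5": 67, "1/x": 19, "1/x^2": 13}
        fits = [_dummy_fit(s, v) for s, v in sums.items()]
        assert select_best_scheme(fits).scheme == "1/y"

    def test_single_fit_returned(self):
        fit = _dummy_fit("1/x", 10)
        assert select_best_scheme([fit]) is fit

    def test_tie_broken_by_correlation(self):
        a = _dummy_fit("1/y", 10, r=0.95)
        b = _dummy_fit("1/x", 10, r=0.99)
        assert select_best_scheme([a, b]) is b

    def test_empty_rejected(self):
        with pytest.raises(NoDataError):
            select_best_scheme([])


class TestDetectionLimits:
    def test_zero_residual_scale(self, exact_line_series):
        lim = detection_limits(fit_ols(exact_line_series))
        assert lim.lod == pytest.approx(0.0, abs=1e-9)
        assert lim.loq == pytest.approx(0.0, abs=1e-9)

    def test_published_ratio_round_trip(self):
        fit = _dummy_fit("1", 0)
        fit.s_y, fit.slope = 0.0179, 1.0
        lim = detection_limits(fit)
        assert lim.lod == pytest.approx(0.0591, abs=5e-4)
        assert lim.loq == pytest.approx(0.179, abs=5e-4)

    def test_loq_lod_ratio_identity(self, noisy_series):
        for scheme in WEIGHT_SCHEMES:
            lim = detection_limits(fit_weighted(noisy_series, scheme))
            assert lim.loq / lim.lod == pytest.approx(10.0 / 3.3, rel=1e-12)

    def test_intercept_basis_switch(self, noisy_series):
        fit = fit_ols(noisy_series)
        lim = detection_limits(fit, basis="intercept")
        assert lim.s_y == pytest.approx(fit.sd_intercept)
        assert lim.basis.endswith(":intercept")

    def test_zero_slope_rejected(self):
        fit = _dummy_fit("1", 0)
        fit.slope = 0.0
        with pytest.raises(LimitsUndefinedError):
            detection_limits(fit)


class TestWeightSchemes:
    def test_unit_weights_reproduce_ols_exactly(self, noisy_series):
        a, b = fit_ols(noisy_series), fit_weighted(noisy_series, "1")
        assert b.slope == pytest.approx(a.slope, rel=1e-10)
        assert b.intercept == pytest.approx(a.intercept, rel=1e-10)
        assert b.r == pytest.approx(a.r, rel=1e-10)

    def test_unknown_scheme_rejected(self, noisy_series):
        with pytest.raises(WeightUndefinedError):
            fit_weighted(noisy_series, "1/z")

    def test_weights_normalized_to_n(self, noisy_series):
        for scheme in WEIGHT_SCHEMES:
            fit = fit_weighted(noisy_series, scheme)
            assert fit.weights.sum() == pytest.approx(fit.n_points)

    def test_inverse_variance_weighting_improves_low_end_backcalc(self):
        # Simulation oracle: with noise sd proportional to the response, the
        # 1/y^2 line back-calculates the lowest level better than OLS in the
        # clear majority of random replicates.
        from chromaval.synthetic_data import CalibrationSimSpec, simulate_calibration

        wins = 0
        n_seeds = 200
        for seed in range(n_seeds):
            series = simulate_calibration(
                CalibrationSimSpec(sigma1=0.05, replicates=3, seed=seed)
            )
            f1 = fit_weighted(series, "1")
            f2 = fit_weighted(series, "1/y^2")
            nrep = series.n_replicates
            low_re_ols = np.abs(f1.pct_re[:nrep]).mean()
            low_re_wls = np.abs(f2.pct_re[:nrep]).mean()
            wins += low_re_wls < low_re_ols
        assert wins > n_seeds / 2


def test_calibrate_summary_structure(noisy_series):
    summary = calibrate(noisy_series)
    assert summary.ols.scheme == "1"
    assert summary.best.scheme in WEIGHT_SCHEMES[1:]
    assert len(summary.fits) == len(WEIGHT_SCHEMES)
    table = summary.table()
    assert set(table["scheme"]) == set(WEIGHT_SCHEMES)
    d = summary.to_dict()
    assert d["selected_scheme"] == summary.best.scheme


def test_too_few_levels_rejected():
    with pytest.raises(FitUndefinedError):
        fit_ols(CalibrationSeries(np.array([1.0, 2.0]), np.array([[1.0], [2.0]])))
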