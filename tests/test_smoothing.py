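"""Spline and fractional-polynomial smoothers and AIC model ranking."""

import numpy as np
import pytest

import refcurve as rc
from refcurve.smoothing import FP_POWERS, PenalizedLS, fp_design


class TestAIC:
    def test_arithmetic(self):
        assert rc.aic(-10.0, 2.0) == 24.0
        assert rc.aic(0.0, 0.0) == 0.0
        assert rc.aic(-5.0, 3.0, penalty_per_df=1.0) == 13.0

    def test_extra_df_costs_penalty(self):
        base = rc.aic(-100.0, 4.0)
        assert rc.aic(-100.0, 5.0) == pytest.approx(base + 2.0)

    def test_negative_edf_rejected(self):
        with pytest.raises(ValueError):
            rc.aic(0.0, -1.0)


@pytest.fixture()
def noisy_sine():
    rng = np.random.default_rng(7)
    t = np.linspace(1.0, 19.0, 200)
    return t, np.sin(t) + rng.normal(0, 0.1, t.size)


class TestCubicSpline:
    def test_reproduces_line_exactly(self):
        t = np.linspace(1, 10, 30)
        y = 2 * t + 1
        for lam in ("auto", 1e-3, 1e6):
            fit = rc.fit_cubic_spline((t, y), smoothing_parameter=lam)
            assert np.max(np.abs(fit.curve(t) - y)) < 1e-6

    def test_infinite_penalty_gives_wls_line(self):
        rng = np.random.default_rng(1)
        t = np.linspace(1, 19, 60)
        y = 3 * t - 5 + rng.normal(0, 1, 60)
        fit = rc.fit_cubic_spline((t, y), smoothing_parameter=1e12)
        assert fit.curve.edf == pytest.approx(2.0, abs=1e-3)
        slope, icept = np.polyfit(t, y, 1)
        assert np.max(np.abs(fit.curve(t) - (slope * t + icept))) < 1e-3

    def test_auto_recovers_smooth_truth(self, noisy_sine):
        t, y = noisy_sine
        fit = rc.fit_cubic_spline((t, y))
        assert np.sqrt(np.mean((fit.curve(t) - np.sin(t)) ** 2)) < 0.1

    def test_too_few_distinct_ages(self):
        with pytest.raises(ValueError, match="distinct"):
            rc.fit_cubic_spline(([1.0, 1.0, 2.0, 3.0], [1, 1, 2, 3]))

    def test_constant_extrapolation(self, noisy_sine):
        t, y = noisy_sine
        c = rc.fit_cubic_spline((t, y)).curve
        assert c(25.0) == pytest.approx(c(19.0))
        assert c(-5.0) == pytest.approx(c(1.0))


class TestPenalizedSpline:
    def test_constant_data(self):
        t = np.linspace(1, 19, 50)
        fit = rc.fit_penalized_spline((t, np.full(50, 4.2)))
        assert np.allclose(fit.curve(t), 4.2, atol=1e-6)
        assert fit.curve.edf < 2.5

    def test_agrees_with_cubic_spline(self, noisy_sine):
        t, y = noisy_sine
        f1 = rc.fit_penalized_spline((t, y))
        f2 = rc.fit_cubic_spline((t, y))
        scale = np.std(y)
        rmse = np.sqrt(np.mean((f1.curve(t) - f2.curve(t)) ** 2))
        assert rmse / scale < 0.02

    def test_unpenalized_large_basis_interpolates(self):
        rng = np.random.default_rng(2)
        t = np.linspace(1, 10, 10)
        y = rng.normal(size=10)
        fit = rc.fit_penalized_spline((t, y), basis_size=16,
                                      smoothing_parameter=1e-10)
        assert np.max(np.abs(fit.curve(t) - y)) < 1e-4

    def test_edf_monotone_in_penalty(self, noisy_sine):
        t, y = noisy_sine
        edfs = [rc.fit_penalized_spline((t, y), smoothing_parameter=lam
                                        ).curve.edf
                for lam in (1e-4, 1e-1, 1e2, 1e5)]
        assert np.all(np.diff(edfs) < 0)

    def test_translation_equivariance_in_value(self, noisy_sine):
        t, y = noisy_sine
        c1 = rc.fit_penalized_spline((t, y), smoothing_parameter=1.0).curve
        c2 = rc.fit_penalized_spline((t, y + 50.0),
                                     smoothing_parameter=1.0).curve
        assert np.allclose(c2(t), c1(t) + 50.0, atol=1e-6)

    def test_bad_basis_rejected(self):
        with pytest.raises(ValueError):
            rc.fit_penalized_spline(([1, 2, 3], [1, 2, 3]), basis_size=2,
                                    difference_order=2)


class TestFractionalPolynomial:
    def test_quadratic_recovered(self):
        t = np.linspace(1, 19, 40)
        fit = rc.fit_fractional_polynomial((t, t**2), degree=2)
        assert 2.0 in fit.powers
        assert np.max(np.abs(fit.curve(t) - t**2)) < 1e-6

    def test_log_recovered(self):
        t = np.linspace(1, 19, 40)
        y = 3.0 + 2.0 * np.log(t)
        fit = rc.fit_fractional_polynomial((t, y), degree=1)
        assert fit.powers == (0.0,)
        assert np.max(np.abs(fit.curve(t) - y)) < 1e-8

    def test_search_equals_full_enumeration(self):
        rng = np.random.default_rng(3)
        t = np.linspace(1, 19, 60)
        y = 100 / t + 5 * np.sqrt(t) + rng.normal(0, 0.5, 60)
        fit = rc.fit_fractional_polynomial((t, y), degree=2)
        # independent oracle: enumerate all 36 power pairs by brute force
        best_rss, best_pair = np.inf, None
        for i, p1 in enumerate(FP_POWERS):
            for p2 in FP_POWERS[i:]:
                X = fp_design(t, (p1, p2))
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = float(np.sum((y - X @ coef) ** 2))
                if rss < best_rss - 1e-12:
                    best_rss, best_pair = rss, (p1, p2)
        assert fit.powers == best_pair

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rc.fit_fractional_polynomial(([-1.0, 1, 2, 3], [1, 1, 2, 3]))


class TestPenalizedLSCore:
    def test_edf_bounds_and_monotonicity(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 1, 100)
        B = np.vander(t, 8, increasing=True)
        D = np.diff(np.eye(8), 2, axis=0)
        pls = PenalizedLS(B, D.T @ D, rng.normal(size=100))
        lams = 10.0 ** np.arange(-6, 7)
        edfs = [pls.edf(l) for l in lams]
        assert np.all(np.diff(edfs) <= 1e-9)
        assert edfs[0] <= 8 + 1e-6 and edfs[-1] >= 2 - 1e-6

    def test_lambda_for_edf_inverts(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 1, 200)
        from refcurve.smoothing import bspline_design, bspline_knots
        knots = bspline_knots(0, 1, 12)
        B = bspline_design(t, knots)
        D = np.diff(np.eye(12), 2, axis=0)
        pls = PenalizedLS(B, D.T @ D, rng.normal(size=200))
        for target in (3.0, 5.0, 8.0):
            lam = pls.lambda_for_edf(target)
            assert pls.edf(lam) == pytest.approx(target, abs=1e-3)


def test_smoother_dispatch():
    t = np.linspace(1, 10, 30)
    fit = rc.fit_smoother("cubic_spline", (t, 2 * t))
    assert fit.curve.method == "cubic_spline"
    with pytest.raises(ValueError, match="unknown smoother"):
        rc.fit_smoother("lowess", (t, t))
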