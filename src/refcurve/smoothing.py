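"""Scatterplot smoothers used to turn discrete reference limits into curves.

Three smoothers are provided, mirroring the candidates commonly compared
when smoothing age-binned reference limits:

* a cubic smoothing spline (integrated squared second-derivative penalty,
  smoothing parameter by generalized cross-validation),
* a penalized B-spline (P-spline: difference penalty on the coefficients,
  smoothing parameter by profile maximum likelihood on the mixed-model
  representation),
* fractional polynomials of degree 1 or 2 over the standard power set
  {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (power 0 denoting log).

All three return a :class:`SmootherFit` carrying the curve, its effective
degrees of freedom, Gaussian log-likelihood and AIC, so that candidate
smoothers can be ranked on equal footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .curves import QuantileCurve

__all__ = [
    "SmootherFit",
    "aic",
    "fit_cubic_spline",
    "fit_penalized_spline",
    "fit_fractional_polynomial",
    "fit_smoother",
    "FP_POWERS",
]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def aic(loglik: float, edf: float, penalty_per_df: float = 2.0) -> float:
    """Akaike information criterion ``-2*loglik + penalty_per_df*edf``.

    The conventional penalty is 2 per effective degree of freedom; the
    penalty is exposed so alternative per-df charges can be used.  Smaller
    is better.
    """
    if edf < 0:
        raise ValueError("edf must be non-negative")
    return -2.0 * loglik + penalty_per_df * edf


@dataclass
class SmootherFit:
    """A fitted scatterplot smoother and its model-selection summaries."""

    curve: QuantileCurve
    aic: float
    smoothing_parameter: float
    knots: np.ndarray


# ---------------------------------------------------------------------------
# penalized least-squares core
# ---------------------------------------------------------------------------


class PenalizedLS:
    """Weighted ridge-type regression ``min ||y - B c||^2_W + lam * c'S c``.

    Shared numerical core for the spline smoothers, the GAMLSS backfitting
    updates and the radial moment regressions.  A single eigendecomposition
    in the whitened coordinate system makes the effective degrees of
    freedom, the residual sum of squares, and the GCV / profile-ML scores
    cheap scalar functions of the smoothing parameter.
    """

    def __init__(self, B: np.ndarray, S: np.ndarray, y: np.ndarray,
                 w: np.ndarray | None = None):
        B = np.asarray(B, float)
        S = np.asarray(S, float)
        y = np.asarray(y, float)
        n, k = B.shape
        if w is None:
            w = np.ones(n)
        w = np.asarray(w, float)
        if np.any(w < 0):
            raise ValueError("negative weights")
        C = (B * w[:, None]).T @ B
        scale = np.trace(C) / k + 1.0
        L = None
        for jitter in (1e-13, 1e-10, 1e-7):
            Cj = C.copy()
            Cj[np.diag_indices_from(Cj)] += jitter * scale
            try:
                L = np.linalg.cholesky(Cj)
                break
            except np.linalg.LinAlgError:
                continue
        if L is None:
            raise ValueError("rank-deficient design: basis larger than the "
                             "information in the data supports")
        # whiten: M = L^{-1} S L^{-T}; eigendecompose once
        tmp = solve_triangular(L, S, lower=True)
        M = solve_triangular(L, tmp.T, lower=True)
        M = 0.5 * (M + M.T)
        lam_eig, U = np.linalg.eigh(M)
        lam_eig = np.clip(lam_eig, 0.0, None)
        # zero out numerically-null eigenvalues so the penalty null space
        # (e.g. linear trends) is reproduced exactly at any lambda
        if lam_eig.max() > 0:
            lam_eig[lam_eig < 1e-10 * lam_eig.max()] = 0.0
        b = B.T @ (w * y)
        g = U.T @ solve_triangular(L, b, lower=True)
        self.B, self.S, self.y, self.w = B, S, y, w
        self.n, self.k = n, k
        self._L, self._U = L, U
        self.eig = lam_eig
        self._g = g
        self._yWy = float(y @ (w * y))
        self._b = b

    # -- scalar-in-lambda summaries ------------------------------------
    def edf(self, lam: float) -> float:
        return float(np.sum(1.0 / (1.0 + lam * self.eig)))

    def _shrink(self, lam: float) -> np.ndarray:
        return 1.0 / (1.0 + lam * self.eig)

    def rss(self, lam: float) -> float:
        s = self._shrink(lam)
        g2 = self._g**2
        return max(self._yWy - 2 * np.sum(g2 * s) + np.sum(g2 * s**2), 0.0)

    def penalized_rss(self, lam: float) -> float:
        s = self._shrink(lam)
        return max(self._yWy - np.sum(self._g**2 * s), 0.0)

    def gcv(self, lam: float) -> float:
        denom = max(self.n - self.edf(lam), 1e-8)
        return self.n * self.rss(lam) / denom**2

    def profile_ml(self, lam: float) -> float:
        """-2 x profile (restricted) log-likelihood, up to a constant."""
        pos = self.eig > 1e-12 * max(self.eig.max(), 1.0)
        pen = self.penalized_rss(lam)
        pen = max(pen, 1e-12 * (self._yWy + 1.0))  # guard degenerate fits
        ridge_terms = np.sum(np.log1p(1.0 / (lam * self.eig[pos])))
        return self.n * np.log(pen / self.n) + ridge_terms

    def coef(self, lam: float) -> np.ndarray:
        s = self._shrink(lam)
        theta = s * self._g
        return solve_triangular(self._L, self._U @ theta, lower=True,
                                trans="T")

    # -- smoothing-parameter selection ---------------------------------
    def select(self, criterion: str = "gcv") -> float:
        score = self.gcv if criterion == "gcv" else self.profile_ml
        obj = lambda loglam: score(10.0**loglam)
        grid = np.linspace(-8.0, 10.0, 37)
        vals = [obj(x) for x in grid]
        x0 = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            obj, bounds=(x0 - 1.0, x0 + 1.0), method="bounded",
            options={"xatol": 1e-4})
        return float(10.0**res.x)

    def lambda_for_edf(self, target: float) -> float:
        """Smoothing parameter whose effective df equals ``target``.

        edf is continuous and strictly decreasing in lambda, from k at 0
        to the penalty nullity at infinity; bisection on log-lambda.
        """
        nullity = float(np.sum(self.eig <= 1e-12 * max(self.eig.max(), 1.0)))
        target = float(np.clip(target, nullity + 1e-6, self.k - 1e-6))
        lo, hi = -12.0, 16.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if self.edf(10.0**mid) > target:
                lo = mid
            else:
                hi = mid
        return 10.0 ** (0.5 * (lo + hi))

    def loglik(self, lam: float) -> float:
        """Gaussian log-likelihood with the profile variance rss/n."""
        sigma2 = max(self.rss(lam) / self.n, 1e-300)
        return -0.5 * self.n * (np.log(2 * np.pi * sigma2) + 1.0)


# ---------------------------------------------------------------------------
# B-spline helpers
# ---------------------------------------------------------------------------


def bspline_knots(lo: float, hi: float, n_basis: int, degree: int = 3,
                  quantile_of: np.ndarray | None = None) -> np.ndarray:
    """Full (clamped) knot vector giving ``n_basis`` B-spline functions."""
    n_inner = n_basis - degree + 1
    if n_inner < 2:
        raise ValueError("basis too small for the requested degree")
    if quantile_of is None:
        inner = np.linspace(lo, hi, n_inner)
    else:
        probs = np.linspace(0, 1, n_inner)
        inner = np.quantile(np.asarray(quantile_of, float), probs)
        inner[0], inner[-1] = lo, hi
        inner = np.maximum.accumulate(inner)
        # collapse accidental duplicates from heavy ties
        for i in range(1, len(inner) - 1):
            if inner[i] <= inner[i - 1]:
                inner[i] = inner[i - 1] + 1e-9 * max(hi - lo, 1.0)
    return np.concatenate([[lo] * degree, inner, [hi] * degree])


def bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3,
                   deriv: int = 0) -> np.ndarray:
    x = np.clip(np.asarray(x, float), knots[degree], knots[-degree - 1])
    n_basis = len(knots) - degree - 1
    if deriv == 0:
        return BSpline.design_matrix(x, knots, degree,
                                     extrapolate=False).toarray()
    eye = np.eye(n_basis)
    cols = [BSpline(knots, eye[j], degree).derivative(deriv)(x)
            for j in range(n_basis)]
    return np.column_stack(cols)


def _second_derivative_penalty(knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Gram matrix of second derivatives, exact by 2-pt Gauss per interval.

    Second derivatives of cubic B-splines are piecewise linear, so the
    product is piecewise quadratic and two Gauss-Legendre points per
    inter-knot interval integrate it exactly.
    """
    breaks = np.unique(knots)
    nodes, weights = np.polynomial.legendre.leggauss(2)
    xq, wq = [], []
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        xq.append(0.5 * (a + b) + half * nodes)
        wq.append(half * weights)
    xq = np.concatenate(xq)
    wq = np.concatenate(wq)
    D2 = bspline_design(xq, knots, degree, deriv=2)
    return (D2 * wq[:, None]).T @ D2


def _coerce_points(points, weights=None):
    """Accept (age, value[, weight]) tuples or separate arrays."""
    if isinstance(points, tuple) and len(points) in (2, 3):
        arrs = [np.asarray(a, float) for a in points]
    else:
        arrs = [np.asarray(a, float) for a in zip(*points)]
    x, y = arrs[0], arrs[1]
    w = arrs[2] if len(arrs) == 3 else None
    if weights is not None:
        w = np.asarray(weights, float)
    if w is None:
        w = np.ones_like(x)
    if x.size != y.size or x.size != w.size:
        raise ValueError("age, value and weight arrays must align")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite point coordinates")
    return x, y, w


def _spline_fit(x, y, w, knots, S, smoothing_parameter, criterion, method):
    B = bspline_design(x, knots)
    pls = PenalizedLS(B, S, y, w)
    if smoothing_parameter in (None, "auto"):
        lam = pls.select(criterion)
    else:
        lam = float(smoothing_parameter)
        if lam < 0:
            raise ValueError("smoothing parameter must be >= 0")
        lam = max(lam, 1e-12)
    coef = pls.coef(lam)
    edf = max(pls.edf(lam), 1.0)
    ll = pls.loglik(lam)
    spl = BSpline(knots, coef, 3)
    lo, hi = knots[3], knots[-4]
    curve = QuantileCurve(None, lambda t: spl(np.clip(t, lo, hi)),
                          (lo, hi), method, edf=edf, loglik=ll)
    return SmootherFit(curve=curve, aic=aic(ll, edf),
                       smoothing_parameter=lam, knots=np.unique(knots))


def fit_cubic_spline(points, smoothing_parameter="auto", weights=None,
                     max_knots: int = 50) -> SmootherFit:
    """Cubic smoothing spline of (age, value[, weight]) points.

    Minimizes the weighted residual sum of squares plus
    ``lam * integral f''(t)^2 dt``; ``smoothing_parameter='auto'`` selects
    lam by generalized cross-validation.  With many distinct ages the
    basis is thinned to ``max_knots`` quantile-spaced knots, the standard
    low-rank representation of a smoothing spline.
    """
    x, y, w = _coerce_points(points, weights)
    xu = np.unique(x)
    if xu.size < 4:
        raise ValueError("need at least 4 distinct ages for a cubic spline")
    n_basis = min(xu.size, max_knots) + 2
    knots = bspline_knots(xu[0], xu[-1], n_basis,
                          quantile_of=x if xu.size > max_knots else None)
    if xu.size <= max_knots:
        inner = np.concatenate([[xu[0]] * 3, xu, [xu[-1]] * 3])
        knots = inner
    S = _second_derivative_penalty(knots)
    return _spline_fit(x, y, w, knots, S, smoothing_parameter, "gcv",
                       "cubic_spline")


def fit_penalized_spline(points, basis_size: int = 20,
                         difference_order: int = 2,
                         smoothing_parameter="auto",
                         weights=None) -> SmootherFit:
    """P-spline: B-spline basis with a difference penalty on coefficients.

    ``smoothing_parameter='auto'`` maximizes the profile likelihood of the
    mixed-model representation (the spline coefficients beyond the
    polynomial null space act as random effects).
    """
    if basis_size < difference_order + 1:
        raise ValueError("basis_size must exceed the difference order")
    x, y, w = _coerce_points(points, weights)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct ages")
    knots = bspline_knots(x.min(), x.max(), basis_size)
    D = np.diff(np.eye(basis_size), difference_order, axis=0)
    S = D.T @ D
    return _spline_fit(x, y, w, knots, S, smoothing_parameter, "ml",
                       "penalized_spline")


def _fp_term(x, p):
    return np.log(x) if p == 0 else x**p


def fp_design(x: np.ndarray, powers: tuple) -> np.ndarray:
    """Fractional-polynomial design matrix (with intercept).

    Repeated powers follow the usual convention: the second occurrence of
    power p contributes ``x^p * log x`` (``(log x)^2`` for p = 0).
    """
    cols = [np.ones_like(x)]
    seen: dict[float, int] = {}
    for p in powers:
        base = _fp_term(x, p)
        reps = seen.get(p, 0)
        cols.append(base * np.log(x) ** reps)
        seen[p] = reps + 1
    return np.column_stack(cols)


def fit_fractional_polynomial(points, degree: int = 2,
                              weights=None) -> SmootherFit:
    """Best-fitting fractional polynomial by exhaustive power search.

    All power tuples from {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (with
    repetition for degree 2) are fitted by weighted least squares and the
    smallest residual sum of squares wins.  Ages must be positive.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x, y, w = _coerce_points(points, weights)
    if np.any(x <= 0):
        raise ValueError("fractional polynomial powers need positive ages")
    if x.size < degree + 2:
        raise ValueError("too few points for the requested degree")
    if degree == 1:
        combos = [(p,) for p in FP_POWERS]
    else:
        combos = [(p1, p2) for i, p1 in enumerate(FP_POWERS)
                  for p2 in FP_POWERS[i:]]
    sw = np.sqrt(w)
    best = None
    for powers in combos:
        X = fp_design(x, powers)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        rss = float(np.sum(w * (y - X @ coef) ** 2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, powers, coef)
    rss, powers, coef = best
    n = x.size
    edf = float(degree + 1)
    sigma2 = max(rss / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    lo, hi = float(x.min()), float(x.max())

    def _eval(t, powers=powers, coef=coef):
        return fp_design(np.atleast_1d(np.clip(t, lo, hi)), powers) @ coef

    curve = QuantileCurve(None, _eval, (lo, hi), "fractional_polynomial",
                          edf=edf, loglik=ll)
    fit = SmootherFit(curve=curve, aic=aic(ll, edf), smoothing_parameter=0.0,
                      knots=np.array([lo, hi]))
    fit.powers = powers  # type: ignore[attr-defined]
    return fit


_SMOOTHERS = {
    "cubic_spline": fit_cubic_spline,
    "penalized_spline": fit_penalized_spline,
    "fractional_polynomial": fit_fractional_polynomial,
}


def fit_smoother(name: str, points, **params) -> SmootherFit:
    """Dispatch a smoother by name (see ``_SMOOTHERS`` keys)."""
    try:
        fn = _SMOOTHERS[name]
    except KeyError:
        raise ValueError(
            f"unknown smoother {name!r}; choose from {sorted(_SMOOTHERS)}"
        ) from None
    return fn(points, **params)
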