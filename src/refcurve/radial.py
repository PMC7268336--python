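"""Radial-smoothing continuous reference intervals.

Stage one fits the conditional mean of value given age by penalized
radial-basis regression (default basis: cubic radial ``|t - kappa|**3``
plus an unpenalized linear part; ridge penalty on the radial coefficients
chosen by generalized cross-validation).  The same machinery applied to
powers of the residuals yields smooth curves for the conditional SD,
skewness and excess kurtosis.  Percentile curves then follow from the
third-order Cornish-Fisher expansion

    w_p(t) = z_p + (z_p**2 - 1)*g1/6 + (z_p**3 - 3 z_p)*g2/24
             - (2 z_p**3 - 5 z_p)*g1**2/36

applied as ``mu(t) + sigma(t) * w_p(t)``.

The expansion is accurate only for mildly non-Gaussian data, so strongly
skewed analytes (ALP around puberty, for instance) should be Box-Cox
transformed first (``transform_first=True``); without the transform the
fit warns and may fail to produce ordered percentile curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .cleaning import BoxCoxParams, boxcox, estimate_boxcox, inverse_boxcox
from .curves import ContinuousRI, CurveCrossingError, QuantileCurve
from .smoothing import PenalizedLS

__all__ = ["RSConfig", "MomentCurves", "fit_moment_curves",
           "cornish_fisher_z", "rs_fit", "edge_diagnostic"]


@dataclass(frozen=True)
class RSConfig:
    """Radial-smoothing settings."""

    n_knots: int = 20
    penalty: str | float = "auto"      # "auto" (GCV) or a fixed value
    basis: str = "cubic_radial"        # or "truncated_polynomial"
    transform_first: bool = False
    #: |gamma1| and |gamma2| caps keeping the Cornish-Fisher expansion
    #: inside its region of validity (and gamma2 above feasibility)
    shape_limits: tuple[float, float] = (1.0, 4.0)

    def __post_init__(self):
        if self.n_knots < 4:
            raise ValueError("need at least 4 knots")
        if self.basis not in ("cubic_radial", "truncated_polynomial"):
            raise ValueError("basis must be 'cubic_radial' or "
                             "'truncated_polynomial'")


@dataclass
class MomentCurves:
    """Smooth curves of the first four conditional moments of value | age."""

    mu: Callable[[np.ndarray], np.ndarray]
    sigma: Callable[[np.ndarray], np.ndarray]
    gamma1: Callable[[np.ndarray], np.ndarray]
    gamma2: Callable[[np.ndarray], np.ndarray]
    knots: np.ndarray
    penalty: float
    age_domain: tuple[float, float]
    edf: float
    loglik: float
    variance_floored: bool = False
    residual_skewness: float = 0.0


def _radial_design(u: np.ndarray, knots_u: np.ndarray, basis: str
                   ) -> np.ndarray:
    if basis == "cubic_radial":
        Z = np.abs(u[:, None] - knots_u[None, :]) ** 3
    else:
        Z = np.maximum(u[:, None] - knots_u[None, :], 0.0) ** 3
    return np.column_stack([np.ones_like(u), u, Z])


def _fit_stage(u, resp, knots_u, basis, penalty):
    B = _radial_design(u, knots_u, basis)
    S = np.eye(B.shape[1])
    S[0, 0] = S[1, 1] = 0.0          # linear part unpenalized
    pls = PenalizedLS(B, S, resp)
    lam = pls.select("gcv") if penalty == "auto" else max(float(penalty), 1e-12)
    coef = pls.coef(lam)
    return coef, lam, pls


def fit_moment_curves(samples: pd.DataFrame, config: RSConfig | None = None
                      ) -> MomentCurves:
    """Sequentially smooth mean, SD, skewness and excess kurtosis vs age.

    Residual powers 2-4 are regressed on age with the same penalized
    radial basis; a negative fitted variance anywhere is floored at a
    small positive value and flagged.
    """
    config = config or RSConfig()
    ages = samples["age"].to_numpy(float)
    y = samples["value"].to_numpy(float)
    if ages.size < 200:
        raise ValueError("need at least 200 records for moment smoothing")
    lo, hi = float(ages.min()), float(ages.max())
    span = hi - lo
    u = (ages - lo) / span
    knots_u = np.linspace(0.0, 1.0, config.n_knots)
    basis = config.basis

    coef_mu, lam, pls = _fit_stage(u, y, knots_u, basis, config.penalty)
    B = pls.B
    resid = y - B @ coef_mu
    # each residual-power regression selects its own GCV penalty: the
    # higher moments are far noisier than the mean and need it
    coef_m2, _, _ = _fit_stage(u, resid**2, knots_u, basis, config.penalty)
    coef_m3, _, _ = _fit_stage(u, resid**3, knots_u, basis, config.penalty)
    coef_m4, _, _ = _fit_stage(u, resid**4, knots_u, basis, config.penalty)

    var_floor = max(1e-6 * float(np.var(y)), 1e-12)
    m2_fit = B @ coef_m2
    floored = bool(np.any(m2_fit <= var_floor))

    def _design_at(t):
        uu = (np.clip(np.asarray(t, float), lo, hi) - lo) / span
        return _radial_design(np.atleast_1d(uu), knots_u, basis)

    def mu_fn(t):
        return _design_at(t) @ coef_mu

    def _m2(t):
        return np.maximum(_design_at(t) @ coef_m2, var_floor)

    def sigma_fn(t):
        return np.sqrt(_m2(t))

    g1_lim, g2_lim = config.shape_limits

    def gamma1_fn(t):
        g1 = (_design_at(t) @ coef_m3) / _m2(t) ** 1.5
        return np.clip(g1, -g1_lim, g1_lim)

    def gamma2_fn(t):
        g2 = (_design_at(t) @ coef_m4) / _m2(t) ** 2 - 3.0
        # feasibility (gamma2 >= gamma1^2 - 2 for any distribution) and
        # the validity region of the Cornish-Fisher expansion
        lo_feas = np.maximum(gamma1_fn(t) ** 2 - 2.0, -g2_lim)
        return np.clip(g2, lo_feas, g2_lim)

    edf = max(pls.edf(lam), 1.0)
    return MomentCurves(mu=mu_fn, sigma=sigma_fn, gamma1=gamma1_fn,
                        gamma2=gamma2_fn,
                        knots=lo + knots_u * span, penalty=lam,
                        age_domain=(lo, hi), edf=edf,
                        loglik=pls.loglik(lam),
                        variance_floored=floored,
                        residual_skewness=float(stats.skew(resid)))


def cornish_fisher_z(p, gamma1, gamma2, include_skew_sq: bool = True):
    """Cornish-Fisher corrected standard score for probability ``p``.

    Third-order expansion in skewness ``gamma1`` and excess kurtosis
    ``gamma2``; ``include_skew_sq=False`` drops the second-order-in-skew
    term.  With both shape terms zero this is exactly the normal quantile.
    """
    p = np.asarray(p, float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    z = stats.norm.ppf(p)
    g1 = np.asarray(gamma1, float)
    g2 = np.asarray(gamma2, float)
    w = z + (z**2 - 1.0) * g1 / 6.0 + (z**3 - 3.0 * z) * g2 / 24.0
    if include_skew_sq:
        w = w - (2.0 * z**3 - 5.0 * z) * g1**2 / 36.0
    return w


def rs_fit(samples: pd.DataFrame, config: RSConfig | None = None,
           percentiles: tuple[float, float] = (0.025, 0.975),
           skew_warn_threshold: float = 0.5) -> ContinuousRI:
    """Radial-smoothing reference interval for one sex stratum.

    With ``config.transform_first`` the values are Box-Cox transformed
    (power by profile ML) before moment smoothing and the percentile
    curves are back-transformed.  Percentile curves that cross raise
    :class:`~refcurve.curves.CurveCrossingError`.
    """
    config = config or RSConfig()
    if samples["sex"].nunique() > 1:
        raise ValueError("fit one sex stratum at a time")
    p_lo, p_hi = percentiles
    if not 0 < p_lo < p_hi < 1:
        raise ValueError("percentiles must satisfy 0 < lo < hi < 1")
    work = samples.copy()
    bc: BoxCoxParams | None = None
    if config.transform_first:
        bc = estimate_boxcox(work["value"].to_numpy(float))
        work["value"] = boxcox(work["value"].to_numpy(float), bc)
    moments = fit_moment_curves(work, config)
    if not config.transform_first and \
            abs(moments.residual_skewness) > skew_warn_threshold:
        warnings.warn(
            f"residual skewness {moments.residual_skewness:.2f} around the "
            "age trend: the moment expansion may not produce effective "
            "reference limits for strongly skewed analytes; consider "
            "transform_first=True", UserWarning)

    def percentile_curve(p):
        def _eval(t, p=p):
            w = cornish_fisher_z(p, moments.gamma1(t), moments.gamma2(t))
            val = moments.mu(t) + moments.sigma(t) * w
            if bc is not None:
                val = inverse_boxcox(val, bc)
            return val
        return QuantileCurve(p, _eval, moments.age_domain, "radial",
                             edf=moments.edf, loglik=moments.loglik)

    lower = percentile_curve(p_lo)
    upper = percentile_curve(p_hi)
    grid = np.linspace(*moments.age_domain, 400)
    lo_v, hi_v = lower(grid), upper(grid)
    if np.any(lo_v >= hi_v):
        bad = grid[lo_v >= hi_v]
        raise CurveCrossingError(
            "radial percentile curves cross between ages "
            f"{bad.min():.2f} and {bad.max():.2f} years (extreme estimated "
            "skewness/kurtosis; try transform_first=True)")
    return ContinuousRI(
        lower=lower, upper=upper, method="rs",
        config={"n_knots": config.n_knots, "basis": config.basis,
                "penalty": moments.penalty,
                "transform_first": config.transform_first,
                "boxcox_lambda": None if bc is None else bc.lam,
                "variance_floored": moments.variance_floored})


def edge_diagnostic(ri: ContinuousRI, samples: pd.DataFrame,
                    window: int = 120) -> dict:
    """Boundary drift: fitted limits vs empirical quantiles of the nearest
    ``window`` subjects at each end of the age domain."""
    s = samples.sort_values("age")
    vals = s["value"].to_numpy(float)
    p_lo = ri.lower.percentile or 0.025
    p_hi = ri.upper.percentile or 0.975
    out = {}
    for side, sl in (("left", slice(0, window)), ("right", slice(-window, None))):
        chunk = vals[sl]
        age_edge = ri.age_domain[0] if side == "left" else ri.age_domain[1]
        emp = np.quantile(chunk, [p_lo, p_hi])
        out[side] = {
            "age": float(age_edge),
            "lower_diff": float(ri.lower(age_edge) - emp[0]),
            "upper_diff": float(ri.upper(age_edge) - emp[1]),
        }
    return out
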