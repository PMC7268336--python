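"""Semi-parametric quantile-curve models: LMS and GAMLSS.

An age-varying Box-Cox family is fitted by penalized maximum likelihood:
each distribution parameter gets its own smooth curve in age,

    log mu(t), log sigma(t), nu(t) [, log tau(t)]

represented as penalized B-splines (difference penalty, fixed effective
degrees of freedom per parameter).  Fitting alternates over the
parameters (backfitting): for the current parameter a quadratic
approximation of the log-likelihood in its predictor gives a working
response and weights, which are smoothed by a weighted P-spline; a
step-halving line search guarantees the global deviance never increases.
The classical LMS model is the special case ``family='BCCG'``; BCT and
BCPE add a kurtosis parameter, by default held constant in age and freed
only when worm-plot diagnostics show residual kurtosis structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import families
from .curves import ContinuousRI, QuantileCurve
from .smoothing import PenalizedLS, aic, bspline_design, bspline_knots

__all__ = ["LSSModel", "WormPlot", "fit", "lms_fit", "gamlss_ri",
           "quantile_curve", "worm_plot", "select_model", "percentile_table",
           "DEFAULT_SMOOTHING"]

#: per-parameter target effective degrees of freedom ("constant" pins the
#: curve to an intercept)
DEFAULT_SMOOTHING = {"mu": 6.0, "sigma": 4.0, "nu": 2.0, "tau": "constant"}

_PARAM_ORDER = ("mu", "sigma", "nu", "tau")
_LOG_LINKED = {"mu", "sigma", "tau"}
_ETA_CLIP = 40.0


@dataclass
class LSSModel:
    """Fitted age-varying Box-Cox family."""

    family: str
    knots: np.ndarray
    degree: int
    coefs: dict
    constant: dict
    edf: dict
    global_deviance: float
    converged: bool
    iterations: int
    age_domain: tuple[float, float]
    n_obs: int
    deviance_path: list = field(default_factory=list)

    @property
    def total_edf(self) -> float:
        return float(sum(self.edf.values()))

    @property
    def aic(self) -> float:
        return aic(-0.5 * self.global_deviance, self.total_edf)

    def _eta(self, name: str, age: np.ndarray) -> np.ndarray:
        age = np.clip(np.asarray(age, float), *self.age_domain)
        B = bspline_design(age, self.knots, self.degree)
        return B @ self.coefs[name]

    def params_at(self, age):
        """(mu, sigma, nu, tau) arrays at the given ages."""
        age = np.atleast_1d(np.asarray(age, float))
        mu = np.exp(self._eta("mu", age))
        sigma = np.exp(self._eta("sigma", age))
        nu = self._eta("nu", age)
        tau = np.exp(self._eta("tau", age)) if "tau" in self.coefs else None
        return mu, sigma, nu, tau

    def quantile(self, p, age):
        mu, sigma, nu, tau = self.params_at(age)
        return families.family_quantile(p, self.family, mu, sigma, nu, tau)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "degree": self.degree,
            "knots": self.knots.tolist(),
            "coefs": {k: v.tolist() for k, v in self.coefs.items()},
            "constant": dict(self.constant),
            "edf": {k: float(v) for k, v in self.edf.items()},
            "global_deviance": self.global_deviance,
            "converged": self.converged,
            "iterations": self.iterations,
            "age_domain": list(self.age_domain),
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSSModel":
        return cls(family=d["family"], knots=np.asarray(d["knots"]),
                   degree=d["degree"],
                   coefs={k: np.asarray(v) for k, v in d["coefs"].items()},
                   constant=d["constant"], edf=d["edf"],
                   global_deviance=d["global_deviance"],
                   converged=d["converged"], iterations=d["iterations"],
                   age_domain=tuple(d["age_domain"]), n_obs=d["n_obs"])


def _loglik_terms(y, family, etas):
    mu = np.exp(np.clip(etas["mu"], -_ETA_CLIP, _ETA_CLIP))
    sigma = np.exp(np.clip(etas["sigma"], -_ETA_CLIP, _ETA_CLIP))
    nu = etas["nu"]
    tau = None
    if "tau" in etas:
        tau = np.exp(np.clip(etas["tau"], -_ETA_CLIP, _ETA_CLIP))
    with np.errstate(all="ignore"):
        ll = families.family_logpdf(y, family, mu, sigma, nu, tau)
    return ll


def _deviance(y, family, etas) -> float:
    ll = _loglik_terms(y, family, etas)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return float(-2.0 * np.sum(ll))


def fit(samples: pd.DataFrame, family: str = "BCCG",
        smoothing: dict | None = None, basis_size: int = 20,
        difference_order: int = 2, max_iter: int = 100,
        tol: float = 1e-4, min_n: int = 200) -> LSSModel:
    """Fit age-varying L/M/S(/tau) curves by penalized backfitting.

    ``smoothing`` maps parameter names to a target effective df or the
    string ``'constant'`` (see :data:`DEFAULT_SMOOTHING`).  The fit is
    deterministic; non-convergence within ``max_iter`` cycles returns the
    model with ``converged=False`` and a warning rather than failing.
    """
    if family not in families.FAMILIES:
        raise ValueError(f"family must be one of {families.FAMILIES}")
    if samples["sex"].nunique() > 1:
        raise ValueError("fit one sex stratum at a time")
    x = samples["age"].to_numpy(float)
    y = samples["value"].to_numpy(float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} records, got {x.size}")
    if np.any(y <= 0):
        raise ValueError("values must be positive")

    smoothing = {**DEFAULT_SMOOTHING, **(smoothing or {})}
    param_names = ["mu", "sigma", "nu"] + (["tau"] if family != "BCCG" else [])

    lo, hi = float(x.min()), float(x.max())
    knots = bspline_knots(lo, hi, basis_size)
    B = bspline_design(x, knots)
    D = np.diff(np.eye(basis_size), difference_order, axis=0)
    S = D.T @ D
    ones = np.ones(basis_size)

    # --- initialization ------------------------------------------------
    coefs: dict[str, np.ndarray] = {}
    constant = {p: smoothing.get(p) == "constant" for p in param_names}
    edf = {p: 1.0 for p in param_names}
    init_mu = PenalizedLS(B, S, np.log(y))
    lam0 = init_mu.lambda_for_edf(float(smoothing["mu"])
                                  if not constant["mu"] else 1.5)
    coefs["mu"] = init_mu.coef(lam0)
    edf["mu"] = init_mu.edf(lam0)
    logr = np.log(y) - B @ coefs["mu"]
    s0 = float(np.clip(np.std(logr), 1e-3, 1.0))
    coefs["sigma"] = np.log(s0) * ones       # B-splines sum to one
    coefs["nu"] = 1.0 * ones
    if "tau" in param_names:
        coefs["tau"] = np.log(10.0 if family == "BCT" else 2.0) * ones

    def etas_of(c):
        out = {p: B @ c[p] for p in param_names}
        return out

    dev = _deviance(y, family, etas_of(coefs))
    if not np.isfinite(dev):
        raise RuntimeError("invalid starting deviance; degenerate data?")
    path = [dev]

    h = 1e-4
    converged = False
    iters = 0
    for it in range(max_iter):
        iters = it + 1
        dev_cycle_start = dev
        for p in param_names:
            etas = etas_of(coefs)
            ll0 = _loglik_terms(y, family, etas)
            eta_p = etas[p]
            etas[p] = eta_p + h
            llp = _loglik_terms(y, family, etas)
            etas[p] = eta_p - h
            llm = _loglik_terms(y, family, etas)
            etas[p] = eta_p
            u = (llp - llm) / (2 * h)
            w = -(llp - 2 * ll0 + llm) / h**2
            ok = np.isfinite(u) & np.isfinite(w)
            u = np.where(ok, u, 0.0)
            # scalar Fisher-information proxy: the mean positive observed
            # curvature.  Per-point observed curvature is unreliable for
            # the scale and shape predictors (it vanishes at z ~ 0 while
            # the score does not), and a constant weight makes the
            # smoothed proposal a descent direction for the deviance.
            wpos = w[ok & (w > 0)]
            wbar = float(np.mean(wpos)) if wpos.size else 1.0
            step = np.clip(u / wbar, -10.0, 10.0)
            z_work = eta_p + step
            old = coefs[p]
            if constant[p]:
                delta = float(np.mean(step))
                cand = old + delta * ones
                new_edf = 1.0
            else:
                pls = PenalizedLS(B, S, z_work, np.full_like(u, wbar))
                lam = pls.lambda_for_edf(float(smoothing[p]))
                cand = pls.coef(lam)
                new_edf = max(pls.edf(lam), 1.0)
            # step-halving line search: deviance must not increase
            accepted = False
            direction = cand - old
            s = 1.0
            for _ in range(12):
                trial = dict(coefs)
                trial[p] = old + s * direction
                dev_trial = _deviance(y, family, etas_of(trial))
                if dev_trial <= dev + 1e-9:
                    coefs[p] = trial[p]
                    dev = dev_trial
                    edf[p] = new_edf if not constant[p] else 1.0
                    accepted = True
                    break
                s *= 0.5
            if not accepted:
                continue
        path.append(dev)
        if not np.isfinite(tol):
            break
        if abs(dev_cycle_start - dev) < tol:
            converged = True
            break

    mu, sigma, nu, tau = (np.exp(B @ coefs["mu"]),
                          np.exp(B @ coefs["sigma"]),
                          B @ coefs["nu"],
                          np.exp(B @ coefs["tau"]) if "tau" in coefs else None)
    if np.any(sigma < 1e-8) or np.any(sigma > 1e3):
        raise RuntimeError("degenerate fitted sigma curve")
    if not converged:
        import warnings
        warnings.warn(f"backfitting did not converge in {iters} cycles "
                      f"(last deviance change {abs(path[-2] - path[-1]):.3g})",
                      RuntimeWarning)

    return LSSModel(family=family, knots=knots, degree=3, coefs=coefs,
                    constant=constant, edf=edf, global_deviance=dev,
                    converged=converged, iterations=iters,
                    age_domain=(lo, hi), n_obs=x.size, deviance_path=path)


def lms_fit(samples: pd.DataFrame, **kw) -> LSSModel:
    """The LMS method: GAMLSS restricted to the Box-Cox normal family."""
    return fit(samples, family="BCCG", **kw)


def quantile_curve(model: LSSModel, p: float, n_grid: int = 200
                   ) -> QuantileCurve:
    """Percentile curve of the fitted model (exact family quantile)."""
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")

    def _eval(t, p=p):
        return model.quantile(p, t)

    return QuantileCurve(p, _eval, model.age_domain, "gamlss",
                         edf=max(model.total_edf, 1.0),
                         loglik=-0.5 * model.global_deviance)


def gamlss_ri(model: LSSModel,
              percentiles: tuple[float, float] = (0.025, 0.975)
              ) -> ContinuousRI:
    """Continuous reference interval from a fitted LMS/GAMLSS model."""
    lo, hi = percentiles
    return ContinuousRI(lower=quantile_curve(model, lo),
                        upper=quantile_curve(model, hi),
                        method="lms" if model.family == "BCCG" else "gamlss",
                        config={"family": model.family,
                                "edf": {k: float(v)
                                        for k, v in model.edf.items()},
                                "converged": model.converged})


def residual_z(model: LSSModel, samples: pd.DataFrame) -> np.ndarray:
    """Normalized quantile residuals; standard normal under a correct model."""
    mu, sigma, nu, tau = model.params_at(samples["age"].to_numpy(float))
    F = families.family_cdf(samples["value"].to_numpy(float), model.family,
                            mu, sigma, nu, tau)
    return stats.norm.ppf(np.clip(F, 1e-12, 1 - 1e-12))


@dataclass
class WormPlot:
    """Detrended per-age-bin QQ diagnostics of model residuals."""

    bins: list            # per bin: dict(q, deviation, band, inside, ages)
    edges: np.ndarray
    flags: list
    dropped: int = 0

    @property
    def misfit_detected(self) -> bool:
        return any(self.flags)

    @property
    def fraction_within_bands(self) -> float:
        tot = sum(len(b["q"]) for b in self.bins)
        inside = sum(int(b["inside"].sum()) for b in self.bins)
        return inside / tot if tot else float("nan")

    def plot(self, path=None):
        """Draw the classical worm-plot panel grid (matplotlib optional)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        k = len(self.bins)
        ncol = int(np.ceil(np.sqrt(k)))
        nrow = int(np.ceil(k / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow),
                                 squeeze=False)
        for ax, b in zip(axes.ravel(), self.bins):
            ax.axhline(0, color="grey", lw=0.5)
            ax.plot(b["q"], b["band"], "r--", lw=0.7)
            ax.plot(b["q"], -b["band"], "r--", lw=0.7)
            ax.plot(b["q"], b["deviation"], "b.", ms=2)
            ax.set_title(f"{b['age_lo']:.1f}-{b['age_hi']:.1f} y", fontsize=8)
        for ax in axes.ravel()[k:]:
            ax.axis("off")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def worm_plot(model: LSSModel, samples: pd.DataFrame, n_bins: int = 9,
              min_bin_n: int = 20, flag_outside_frac: float = 0.10
              ) -> WormPlot:
    """Worm plot: detrended QQ points of quantile residuals per age bin.

    Equal-count age bins; bins with fewer than ``min_bin_n`` points are
    dropped with a notice.  A bin is flagged when more than
    ``flag_outside_frac`` of its points leave the pointwise 95% bands —
    systematic curvature (an S shape, say) signals missing skewness or
    kurtosis in the model.
    """
    ages = samples["age"].to_numpy(float)
    z = residual_z(model, samples)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.quantile(ages, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    bins, flags = [], []
    dropped = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (ages >= lo) & (ages < hi)
        zb = np.sort(z[mask])
        nb = zb.size
        if nb < min_bin_n:
            dropped += 1
            continue
        probs = (np.arange(1, nb + 1) - 0.375) / (nb + 0.25)
        q = stats.norm.ppf(probs)
        dev = zb - q
        band = 1.96 * np.sqrt(probs * (1 - probs) / nb) / stats.norm.pdf(q)
        inside = np.abs(dev) <= band
        bins.append({"age_lo": float(lo), "age_hi": float(hi), "q": q,
                     "deviation": dev, "band": band, "inside": inside})
        flags.append(bool(np.mean(~inside) > flag_outside_frac))
    if not bins:
        raise ValueError("every age bin fell below the minimum point count")
    return WormPlot(bins=bins, edges=edges, flags=flags, dropped=dropped)


def select_model(candidates, samples: pd.DataFrame, **fit_kw):
    """Fit each (family, smoothing) candidate and rank by AIC.

    Returns a list of dicts sorted by AIC (ties broken by smaller total
    edf, then listed order); raises if no candidate converges.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    results = []
    for i, (family, smoothing) in enumerate(candidates):
        model = fit(samples, family=family, smoothing=smoothing, **fit_kw)
        results.append({"order": i, "family": family,
                        "smoothing": smoothing, "model": model,
                        "aic": model.aic, "edf": model.total_edf,
                        "converged": model.converged})
    if not any(r["converged"] for r in results):
        raise RuntimeError("no candidate model converged")
    results.sort(key=lambda r: (not r["converged"], r["aic"], r["edf"],
                                r["order"]))
    return results


def percentile_table(model: LSSModel,
                     percentiles=(0.025, 0.10, 0.25, 0.50, 0.75, 0.90, 0.975),
                     ages=None) -> pd.DataFrame:
    """Seven-percentile age table (one row per age year by default)."""
    if ages is None:
        lo, hi = model.age_domain
        ages = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    ages = np.asarray(ages, float)
    out = {"age": ages}
    for p in percentiles:
        out[f"p{100 * p:g}"] = model.quantile(p, ages)
    return pd.DataFrame(out)
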