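"""Shared curve containers for continuous reference intervals.

A fitted percentile curve is a smooth map from age (decimal years) to an
analyte value, valid on a finite age domain.  Outside the domain the curve
extrapolates with the boundary value, which matches how clinical reference
curves are applied to patients slightly outside the modelled age span.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["QuantileCurve", "ContinuousRI", "CurveCrossingError", "ensure_ordered"]


class CurveCrossingError(ValueError):
    """Raised when a lower percentile curve meets or exceeds an upper one."""


@dataclass
class QuantileCurve:
    """A smooth percentile curve ``age -> value``.

    Parameters
    ----------
    percentile : float or None
        Probability level in (0, 1), e.g. 0.025 for the lower reference
        limit.  ``None`` for generic smoother fits that are not tied to a
        percentile.
    eval_fn : callable
        Vectorized evaluator defined on ``age_domain``.
    age_domain : (float, float)
        Closed age interval on which the curve was fitted.  Evaluation
        outside uses constant extrapolation of the boundary value.
    method : str
        One of ``cubic_spline``, ``penalized_spline``,
        ``fractional_polynomial``, ``stepwise``, ``gamlss``, ``radial``.
    edf : float
        Effective degrees of freedom of the fit.
    loglik : float
        Log-likelihood at the fit (Gaussian working likelihood for
        least-squares smoothers).
    """

    percentile: float | None
    eval_fn: Callable[[np.ndarray], np.ndarray]
    age_domain: tuple[float, float]
    method: str
    edf: float = 1.0
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        lo, hi = self.age_domain
        if not lo < hi:
            raise ValueError(f"degenerate age domain {self.age_domain}")
        if self.percentile is not None and not 0.0 < self.percentile < 1.0:
            raise ValueError("percentile must lie in (0, 1)")
        if self.edf < 1.0 - 1e-8:
            raise ValueError("effective degrees of freedom must be >= 1")

    def __call__(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        clipped = np.clip(age, *self.age_domain)
        out = np.asarray(self.eval_fn(clipped), dtype=float)
        if out.shape != clipped.shape:
            out = out.reshape(clipped.shape)
        return out

    def sample(self, n_grid: int = 200) -> "np.ndarray":
        """Return an ``(n_grid, 2)`` array of (age, value) pairs."""
        grid = np.linspace(*self.age_domain, n_grid)
        return np.column_stack([grid, self(grid)])


def ensure_ordered(lower: QuantileCurve, upper: QuantileCurve,
                   n_grid: int = 400) -> None:
    """Verify ``lower(t) < upper(t)`` on a dense grid of the shared domain.

    Raises :class:`CurveCrossingError` naming the offending age interval;
    smoothed limits can cross when the discrete limits are noisy (observed
    in practice for fractional-polynomial smoothing of ALP limits).
    """
    lo = max(lower.age_domain[0], upper.age_domain[0])
    hi = min(lower.age_domain[1], upper.age_domain[1])
    grid = np.linspace(lo, hi, n_grid)
    bad = lower(grid) >= upper(grid)
    if bad.any():
        ages = grid[bad]
        raise CurveCrossingError(
            "lower and upper percentile curves cross between ages "
            f"{ages.min():.2f} and {ages.max():.2f} years"
        )


@dataclass
class ContinuousRI:
    """A continuous reference interval: lower and upper percentile curves."""

    lower: QuantileCurve
    upper: QuantileCurve
    method: str
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ensure_ordered(self.lower, self.upper)

    @property
    def age_domain(self) -> tuple[float, float]:
        lo = max(self.lower.age_domain[0], self.upper.age_domain[0])
        hi = min(self.lower.age_domain[1], self.upper.age_domain[1])
        return (lo, hi)

    def limits(self, age) -> tuple[np.ndarray, np.ndarray]:
        return self.lower(age), self.upper(age)

    def to_dict(self, n_grid: int = 200) -> dict:
        grid = np.linspace(*self.age_domain, n_grid)
        return {
            "method": self.method,
            "config": _jsonable(self.config),
            "age_domain": list(self.age_domain),
            "percentiles": [self.lower.percentile, self.upper.percentile],
            "edf": [self.lower.edf, self.upper.edf],
            "loglik": [self.lower.loglik, self.upper.loglik],
            "age_grid": grid.tolist(),
            "lower": self.lower(grid).tolist(),
            "upper": self.upper(grid).tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, allow_nan=True)

    def curve_table(self, n_grid: int = 200):
        """(age, lower, upper) sampled on a uniform grid, as a DataFrame."""
        import pandas as pd

        grid = np.linspace(*self.age_domain, n_grid)
        return pd.DataFrame(
            {"age": grid, "lower": self.lower(grid), "upper": self.upper(grid)}
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
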