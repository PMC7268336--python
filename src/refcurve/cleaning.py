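"""Outlier removal for cohort tables.

Within each (sex, one-year age) group, Tukey's fences flag records below
``Q1 - 1.5*IQR`` or above ``Q3 + 1.5*IQR``.  The fence logic assumes an
approximately Gaussian group; when a normality check rejects, the group is
first Box-Cox transformed (power chosen by profile maximum likelihood)
and the fences are applied on the transformed scale, where the quartile
geometry is meaningful again.  Because the transform is strictly
increasing, flagging on the transformed scale is equivalent to flagging
against back-transformed fences.

Quantile convention, package-wide: linear interpolation of order
statistics (numpy's default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BoxCoxParams", "CleaningReport", "GroupReport",
           "boxcox", "inverse_boxcox", "estimate_boxcox", "tukey_fences",
           "clean"]

#: lambda search grid for the profile-likelihood estimate
BOXCOX_GRID = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.01), 2)


@dataclass(frozen=True)
class BoxCoxParams:
    """Box-Cox power ``lambda`` and shift ``c`` (shift used when lambda=0)."""
    lam: float
    c: float = 0.0


def boxcox(values, params: BoxCoxParams):
    """Box-Cox transform: ``(x**lam - 1)/lam``, or ``ln(x + c)`` at lam=0.

    Strictly increasing in x for any fixed parameters.
    """
    x = np.asarray(values, float)
    lam, c = params.lam, params.c
    if lam == 0:
        if np.any(x + c <= 0):
            raise ValueError("x + c must be positive for the log branch")
        return np.log(x + c)
    if lam != int(lam) and np.any(x <= 0):
        raise ValueError("x must be positive for non-integer lambda")
    return (np.power(x, lam) - 1.0) / lam


def inverse_boxcox(y, params: BoxCoxParams):
    """Invert :func:`boxcox`; domain requires ``lam*y + 1 > 0`` for lam != 0."""
    y = np.asarray(y, float)
    lam, c = params.lam, params.c
    if lam == 0:
        return np.exp(y) - c
    arg = lam * y + 1.0
    if np.any(arg <= 0):
        raise ValueError("lam*y + 1 must be positive to invert the transform")
    return np.power(arg, 1.0 / lam)


def estimate_boxcox(values, grid=BOXCOX_GRID) -> BoxCoxParams:
    """Profile-ML Box-Cox power over a fixed grid (shift c = 0).

    Maximizes the Gaussian log-likelihood of the transformed sample,
    including the Jacobian term ``(lam - 1) * sum(log x)``.  Requires at
    least 20 positive values — the estimate is unstable below that.
    """
    x = np.asarray(values, float)
    if x.size < 20:
        raise ValueError("need at least 20 values to estimate lambda")
    if np.any(x <= 0):
        raise ValueError("Box-Cox estimation needs positive values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values equal, lambda "
                         "undefined")
    llf = np.array([stats.boxcox_llf(lam, x) for lam in grid])
    return BoxCoxParams(lam=float(grid[int(np.argmax(llf))]), c=0.0)


def tukey_fences(values) -> tuple[float, float]:
    """``(Q1 - 1.5*IQR, Q3 + 1.5*IQR)`` with linear-interpolation quartiles."""
    x = np.asarray(values, float)
    if x.size < 4:
        raise ValueError("need at least 4 values for Tukey fences")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


@dataclass
class GroupReport:
    sex: str
    age_year: int
    n_before: int
    n_removed_low: int = 0
    n_removed_high: int = 0
    transform_applied: bool = False
    boxcox_lambda: float | None = None
    fences: tuple[float, float] | None = None
    normality_p: float | None = None
    skipped: bool = False

    @property
    def n_after(self) -> int:
        return self.n_before - self.n_removed_low - self.n_removed_high


@dataclass
class CleaningReport:
    groups: list = field(default_factory=list)

    @property
    def n_before(self) -> int:
        return sum(g.n_before for g in self.groups)

    @property
    def n_removed(self) -> int:
        return sum(g.n_removed_low + g.n_removed_high for g in self.groups)

    def to_dict(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_removed": self.n_removed,
            "groups": [
                {"sex": g.sex, "age_year": g.age_year,
                 "n_before": g.n_before,
                 "n_removed_low": g.n_removed_low,
                 "n_removed_high": g.n_removed_high,
                 "transform_applied": g.transform_applied,
                 "boxcox_lambda": g.boxcox_lambda,
                 "fences": list(g.fences) if g.fences else None,
                 "normality_p": g.normality_p,
                 "skipped": g.skipped}
                for g in self.groups
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def clean(samples: pd.DataFrame, alpha: float = 0.05,
          transform: str = "auto", min_group: int = 4,
          min_normality_n: int = 20) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove outliers per (sex, one-year age) group by Tukey's method.

    ``transform`` controls the decision scale: ``'auto'`` (Shapiro-Wilk at
    ``alpha`` decides whether to Box-Cox first; groups smaller than
    ``min_normality_n`` skip the test and use the raw scale), ``'always'``
    or ``'never'``.  Groups with fewer than ``min_group`` records pass
    through untouched and are flagged in the report.
    """
    if len(samples) == 0:
        raise ValueError("empty sample table")
    if transform not in ("auto", "always", "never"):
        raise ValueError("transform must be 'auto', 'always' or 'never'")
    samples = samples.reset_index(drop=True)
    report = CleaningReport()
    keep = np.ones(len(samples), bool)
    ages = samples["age"].to_numpy(float)
    age_year = np.floor(ages).astype(int)
    for (sex, year), idx in samples.groupby(
            [samples["sex"], age_year], sort=True).groups.items():
        pos = samples.index.get_indexer(idx)
        vals = samples["value"].to_numpy(float)[pos]
        g = GroupReport(sex=sex, age_year=int(year), n_before=vals.size)
        if vals.size < min_group:
            g.skipped = True
            report.groups.append(g)
            continue
        decision = vals
        do_transform = transform == "always"
        if transform == "auto" and vals.size >= min_normality_n:
            if np.ptp(vals) > 0:
                g.normality_p = float(stats.shapiro(vals).pvalue)
                do_transform = g.normality_p < alpha
        if do_transform and np.ptp(vals) > 0 and vals.size >= 20:
            params = estimate_boxcox(vals)
            g.boxcox_lambda = params.lam
            g.transform_applied = True
            decision = boxcox(vals, params)
        lo, hi = tukey_fences(decision)
        g.fences = (lo, hi)
        out_lo = decision < lo
        out_hi = decision > hi
        g.n_removed_low = int(out_lo.sum())
        g.n_removed_high = int(out_hi.sum())
        keep[pos[out_lo | out_hi]] = False
        report.groups.append(g)
    cleaned = samples.loc[keep].reset_index(drop=True)
    return cleaned, report
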