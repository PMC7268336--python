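"""Hold-out validation of continuous reference intervals.

The cohort is split, per sex, into training and test sets in an 8:2
ratio; the split is accepted only when a two-sided Wilcoxon rank-sum test
finds no age-distribution difference between the parts (P >= 0.05),
otherwise it is redrawn.  Each candidate method is fitted on the training
set and judged by its out-of-range (OOR) percentage on the test set: the
share of held-out healthy subjects falling below the lower or above the
upper limit.  A 95% interval is correctly calibrated at about 5% total
(2.5% per tail); by CLSI convention an interval is acceptable while the
total stays below 10%.  Splitting, fitting and scoring are repeated (100
times in the full design) and OOR summaries are averaged per method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .curves import ContinuousRI, QuantileCurve
from .gamlss import fit as gamlss_fit_op
from .gamlss import gamlss_ri
from .nonparametric import FrameConfig, nonparametric_fit
from .radial import RSConfig, rs_fit

__all__ = ["SplitResult", "OORResult", "ComparisonReport",
           "split", "oor", "discrete_baseline", "run_comparison",
           "standard_methods", "OOR_VALIDITY_BOUND"]

#: CLSI acceptability bound on the total out-of-range percentage
OOR_VALIDITY_BOUND = 10.0


@dataclass
class SplitResult:
    train: pd.DataFrame
    test: pd.DataFrame
    wilcoxon_p: float
    attempts: int
    seed: int


def split(samples: pd.DataFrame, ratio: tuple[float, float] = (0.8, 0.2),
          seed: int = 0, max_attempts: int = 50,
          alpha: float = 0.05) -> SplitResult:
    """Sex-stratified random 8:2 split with a Wilcoxon age check.

    The rank-sum test (two-sided, normal approximation with continuity
    correction) compares train and test age distributions; a split with
    P < ``alpha`` is redrawn with the next sub-seed, up to
    ``max_attempts`` times.
    """
    if not np.isclose(sum(ratio), 1.0):
        raise ValueError("ratio must sum to 1")
    counts = samples.groupby("sex").size()
    if (counts < 50).any():
        raise ValueError("need at least 50 records per sex to split")
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        train_mask = np.zeros(len(samples), bool)
        for _, idx in samples.groupby("sex").indices.items():
            perm = rng.permutation(idx)
            n_train = int(round(ratio[0] * len(idx)))
            train_mask[perm[:n_train]] = True
        train = samples.loc[train_mask].reset_index(drop=True)
        test = samples.loc[~train_mask].reset_index(drop=True)
        p = float(stats.mannwhitneyu(
            train["age"], test["age"], alternative="two-sided",
            use_continuity=True, method="asymptotic").pvalue)
        if p >= alpha:
            return SplitResult(train=train, test=test, wilcoxon_p=p,
                               attempts=attempt + 1, seed=seed)
    raise RuntimeError(
        f"no acceptable split in {max_attempts} attempts (seed {seed})")


@dataclass
class OORResult:
    """Out-of-range percentages of a reference interval on held-out data."""

    total_pct: float
    lower_pct: float
    upper_pct: float
    n_test: int
    per_age: pd.DataFrame = field(repr=False, default=None)


def oor(ri: ContinuousRI, test: pd.DataFrame) -> OORResult:
    """Percentage of test records outside the interval, overall and per
    one-year age bin ``[k, k+1)``."""
    if len(test) == 0:
        raise ValueError("empty test set")
    ages = test["age"].to_numpy(float)
    vals = test["value"].to_numpy(float)
    below = vals < ri.lower(ages)
    above = vals > ri.upper(ages)
    n = len(test)
    year = np.floor(ages).astype(int)
    rows = []
    for k in np.unique(year):
        m = year == k
        nk = int(m.sum())
        rows.append({"age_year": int(k), "n": nk,
                     "lower_pct": 100.0 * below[m].sum() / nk,
                     "upper_pct": 100.0 * above[m].sum() / nk,
                     "total_pct": 100.0 * (below[m] | above[m]).sum() / nk})
    per_age = pd.DataFrame(rows)
    return OORResult(total_pct=100.0 * (below | above).sum() / n,
                     lower_pct=100.0 * below.sum() / n,
                     upper_pct=100.0 * above.sum() / n,
                     n_test=n, per_age=per_age)


def discrete_baseline(train: pd.DataFrame, bin_years: float = 1.0,
                      percentiles: tuple[float, float] = (0.025, 0.975),
                      min_bin_n: int = 120) -> ContinuousRI:
    """Fixed-width age-bin empirical limits as step-function curves.

    The conventional discrete reference interval: one pair of empirical
    percentiles per age bin, appearing as a ladder over age.  Empty bins
    are merged with their left neighbour; bins below ``min_bin_n``
    records (the CLSI minimum) are flagged in the config.
    """
    ages = train["age"].to_numpy(float)
    vals = train["value"].to_numpy(float)
    lo_age, hi_age = float(np.floor(ages.min())), float(ages.max())
    edges = np.arange(lo_age, hi_age + bin_years, bin_years)
    if edges[-1] <= hi_age:
        edges = np.append(edges, hi_age + 1e-9)
    groups, small_bins, merged = [], [], 0
    start = 0
    for i in range(len(edges) - 1):
        mask = (ages >= edges[start]) & (ages < edges[i + 1])
        if mask.sum() == 0:
            merged += 1
            continue
        groups.append((edges[start], edges[i + 1], vals[mask]))
        start = i + 1
    if not groups:
        raise ValueError("no data in any age bin")
    bin_edges = np.array([g[0] for g in groups] + [groups[-1][1]])
    lows = np.array([np.quantile(g[2], percentiles[0]) for g in groups])
    highs = np.array([np.quantile(g[2], percentiles[1]) for g in groups])
    small_bins = [float(g[0]) for g in groups if g[2].size < min_bin_n]

    def step_eval(values):
        def _eval(t):
            t = np.atleast_1d(np.asarray(t, float))
            idx = np.clip(np.searchsorted(bin_edges, t, side="right") - 1,
                          0, len(values) - 1)
            return values[idx]
        return _eval

    domain = (float(bin_edges[0]), float(bin_edges[-1]))
    k = float(len(groups))
    lower = QuantileCurve(percentiles[0], step_eval(lows), domain,
                          "stepwise", edf=k)
    upper = QuantileCurve(percentiles[1], step_eval(highs), domain,
                          "stepwise", edf=k)
    return ContinuousRI(lower=lower, upper=upper, method="discrete",
                        config={"bin_years": bin_years,
                                "bins_merged": merged,
                                "small_bins": small_bins})


def standard_methods(frame_config: FrameConfig | None = None,
                     rs_config: RSConfig | None = None,
                     gamlss_family: str = "BCPE") -> dict:
    """The four continuous-RI methods under their published configurations.

    Returns name -> fitter(train, seed) callables: improved non-parametric
    (n=120, m=2, penalized-spline smoothing), radial smoothing with a
    Box-Cox pre-transform, LMS (BCCG) and GAMLSS (BCPE by default), all
    at the package's default smoothing settings.
    """
    fc = frame_config or FrameConfig()
    rc = rs_config or RSConfig(transform_first=True)

    def _np_fit(train, seed):
        return nonparametric_fit(train, fc, smoother="penalized_spline",
                                 seed=seed)

    def _rs_fit(train, seed):
        return rs_fit(train, rc)

    def _lms(train, seed):
        return gamlss_ri(gamlss_fit_op(train, family="BCCG"))

    def _gamlss(train, seed):
        return gamlss_ri(gamlss_fit_op(train, family=gamlss_family))

    return {"nonparametric": _np_fit, "rs": _rs_fit,
            "lms": _lms, "gamlss": _gamlss}


@dataclass
class ComparisonReport:
    """Mean/SD of OOR summaries over repeated splits, per method."""

    table: pd.DataFrame
    repetitions: int
    failures: dict

    def valid(self, method: str) -> bool:
        row = self.table.loc[self.table["method"] == method]
        if row.empty:
            return False
        return bool(row["total_mean"].iloc[0] < OOR_VALIDITY_BOUND)


def run_comparison(samples: pd.DataFrame, methods: dict,
                   repetitions: int = 100, base_seed: int = 0,
                   ratio: tuple[float, float] = (0.8, 0.2)
                   ) -> ComparisonReport:
    """Repeat split -> fit -> OOR for every method and aggregate.

    ``methods`` maps a name to ``fitter(train, seed) -> ContinuousRI``.
    A method that fails on more than half the repetitions is reported as
    failed (NaN summaries); the run continues for the others.
    """
    if not methods:
        raise ValueError("no methods given")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    records: dict[str, list[OORResult]] = {m: [] for m in methods}
    failures: dict[str, int] = {m: 0 for m in methods}
    for r in range(repetitions):
        sp = split(samples, ratio=ratio, seed=base_seed + r)
        for name, fitter in methods.items():
            try:
                ri = fitter(sp.train, base_seed + r)
                records[name].append(oor(ri, sp.test))
            except Exception:
                failures[name] += 1
    rows = []
    for name in methods:
        res = records[name]
        if failures[name] > repetitions / 2 or not res:
            rows.append({"method": name, "n_ok": len(res),
                         "failed": True,
                         "total_mean": np.nan, "total_sd": np.nan,
                         "lower_mean": np.nan, "lower_sd": np.nan,
                         "upper_mean": np.nan, "upper_sd": np.nan})
            continue
        tot = np.array([o.total_pct for o in res])
        lo = np.array([o.lower_pct for o in res])
        hi = np.array([o.upper_pct for o in res])
        rows.append({"method": name, "n_ok": len(res), "failed": False,
                     "total_mean": tot.mean(),
                     "total_sd": tot.std(ddof=1) if len(res) > 1 else 0.0,
                     "lower_mean": lo.mean(),
                     "lower_sd": lo.std(ddof=1) if len(res) > 1 else 0.0,
                     "upper_mean": hi.mean(),
                     "upper_sd": hi.std(ddof=1) if len(res) > 1 else 0.0})
    return ComparisonReport(table=pd.DataFrame(rows),
                            repetitions=repetitions, failures=failures)
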