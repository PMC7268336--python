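"""Synthetic pediatric cohorts for exercising the reference-interval pipeline.

Two generators are provided:

* :func:`generate_cohort` draws a cohort from a :class:`CohortSpec` — a set
  of per-age-bin sample sizes, means and SDs.  Presets calibrated to the
  published per-age summary statistics of alkaline phosphatase (ALP, U/L)
  and serum creatinine (Cr, umol/L) in a healthy pediatric reference
  population aged 1-19 are built in via :func:`table1_preset`.  These reproduce the analytes'
  characteristic age trends: ALP rises through childhood, peaks around
  puberty and then falls steeply; Cr increases monotonically with age.
* :func:`generate_from_truth` draws from a Box-Cox normal model with known
  age-varying skewness L(t), median M(t) and coefficient of variation
  S(t), so that fitted percentile curves can be compared with closed-form
  truth in parameter-recovery tests.

Only age and sex structure is modelled; site, instrument and other
covariate effects are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import families

__all__ = [
    "AgeBin", "CohortSpec", "LSSTruth",
    "table1_preset", "generate_cohort", "generate_from_truth",
    "read_cohort", "write_cohort", "validate_samples",
    "ANALYTES", "SEXES",
]

ANALYTES = ("ALP", "Cr")
SEXES = ("boy", "girl")


@dataclass(frozen=True)
class AgeBin:
    """One age bin: [age_lo, age_hi) with its sample size, mean and SD."""
    age_lo: float
    age_hi: float
    n: int
    mean: float
    sd: float


@dataclass
class CohortSpec:
    """Per-age-bin moments from which a synthetic cohort is drawn."""

    analyte: str
    sex: str
    bins: Sequence[AgeBin]
    value_floor: float = 1.0
    shape: str = "gaussian"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.shape not in ("gaussian", "lognormal"):
            raise ValueError("shape must be 'gaussian' or 'lognormal'")
        if self.value_floor <= 0:
            raise ValueError("value_floor must be positive")
        self.bins = [b if isinstance(b, AgeBin) else AgeBin(*b)
                     for b in self.bins]
        prev_hi = None
        for b in self.bins:
            if not (1.0 <= b.age_lo < b.age_hi <= 20.0):
                raise ValueError(f"bin [{b.age_lo}, {b.age_hi}) outside [1, 20)")
            if prev_hi is not None and b.age_lo < prev_hi - 1e-12:
                raise ValueError("bins must be ordered and non-overlapping")
            if b.n < 1 or b.sd <= 0 or b.mean <= self.value_floor:
                raise ValueError(f"invalid bin moments {b}")
            prev_hi = b.age_hi

    @property
    def n_total(self) -> int:
        return int(sum(b.n for b in self.bins))

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte, "sex": self.sex,
            "value_floor": self.value_floor, "shape": self.shape,
            "bins": [[b.age_lo, b.age_hi, b.n, b.mean, b.sd]
                     for b in self.bins],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(analyte=d["analyte"], sex=d["sex"],
                   bins=[AgeBin(*b) for b in d["bins"]],
                   value_floor=d.get("value_floor", 1.0),
                   shape=d.get("shape", "gaussian"))

    @classmethod
    def from_file(cls, path) -> "CohortSpec":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class LSSTruth:
    """Known L(t), M(t), S(t) curves of a Box-Cox normal ground truth."""

    nu_fn: Callable[[np.ndarray], np.ndarray]
    mu_fn: Callable[[np.ndarray], np.ndarray]
    sigma_fn: Callable[[np.ndarray], np.ndarray]
    age_range: tuple[float, float] = (1.0, 19.0)

    def params_at(self, age):
        age = np.asarray(age, float)
        mu = np.asarray(self.mu_fn(age), float)
        sigma = np.asarray(self.sigma_fn(age), float)
        nu = np.asarray(self.nu_fn(age), float)
        if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
            raise ValueError("mu_fn must be positive and finite on age_range")
        if np.any(~np.isfinite(sigma)) or np.any(sigma <= 0):
            raise ValueError("sigma_fn must be positive and finite on age_range")
        if np.any(~np.isfinite(nu)):
            raise ValueError("nu_fn must be finite on age_range")
        return nu, mu, sigma

    def quantile(self, p, age):
        """Closed-form percentile curve of the generating distribution."""
        nu, mu, sigma = self.params_at(age)
        return families.family_quantile(p, "BCCG", mu, sigma, nu)


# ---------------------------------------------------------------------------
# Published per-age-bin summary statistics (n, mean, SD) for ALP and Cr,
# healthy children aged 1-19, by sex.  Bin k spans [k, k+1) years.
# ---------------------------------------------------------------------------

_TABLE1 = {
    ("ALP", "boy"): [
        (255, 253.96, 62.55), (304, 228.59, 47.73), (446, 222.06, 45.83),
        (287, 214.88, 42.28), (286, 226.13, 47.68), (393, 227.92, 43.78),
        (413, 231.92, 52.08), (401, 240.51, 53.58), (396, 247.88, 58.34),
        (426, 256.03, 61.68), (298, 283.69, 75.29), (408, 325.02, 92.31),
        (283, 319.35, 97.79), (230, 266.79, 99.06), (309, 178.57, 80.91),
        (196, 132.40, 49.03), (162, 103.91, 28.26), (113, 91.61, 18.18),
        (63, 83.44, 19.79),
    ],
    ("ALP", "girl"): [
        (225, 243.68, 50.98), (266, 236.15, 55.18), (337, 220.36, 45.17),
        (298, 224.49, 47.75), (280, 233.63, 47.95), (355, 230.68, 47.52),
        (372, 237.97, 51.65), (405, 250.31, 58.60), (371, 261.05, 64.72),
        (390, 283.31, 61.18), (287, 272.87, 68.94), (356, 226.99, 83.11),
        (315, 178.50, 68.13), (239, 137.99, 49.86), (383, 100.32, 33.80),
        (244, 87.52, 24.61), (264, 74.55, 18.27), (293, 70.80, 15.47),
        (168, 69.28, 14.40),
    ],
    ("Cr", "boy"): [
        (260, 24.85, 3.52), (309, 28.58, 4.02), (449, 32.61, 4.23),
        (286, 35.14, 4.36), (289, 37.18, 4.32), (392, 40.90, 5.34),
        (409, 41.93, 4.95), (402, 44.04, 5.41), (386, 46.33, 5.14),
        (422, 48.99, 5.85), (299, 49.87, 6.12), (410, 55.62, 8.52),
        (282, 59.66, 9.65), (232, 66.92, 11.03), (307, 75.27, 10.84),
        (198, 77.84, 11.09), (164, 79.58, 10.25), (115, 78.51, 9.76),
        (63, 84.51, 8.72),
    ],
    ("Cr", "girl"): [
        (227, 23.78, 3.33), (273, 28.61, 4.46), (328, 31.08, 3.50),
        (300, 34.24, 4.34), (284, 36.95, 4.50), (362, 40.02, 4.99),
        (378, 40.93, 5.02), (405, 43.02, 5.59), (369, 45.15, 5.23),
        (391, 45.36, 5.19), (293, 45.75, 6.25), (353, 51.64, 7.93),
        (319, 53.46, 8.10), (240, 55.65, 7.73), (375, 60.77, 7.39),
        (247, 61.43, 8.25), (264, 61.55, 7.87), (297, 60.16, 7.92),
        (165, 59.67, 6.85),
    ],
}


def table1_preset(analyte: str, sex: str, shape: str = "gaussian") -> CohortSpec:
    """Cohort specification calibrated to the published ALP / Cr summaries.

    ``analyte`` is ``'ALP'`` or ``'Cr'``; ``sex`` is ``'boy'`` or
    ``'girl'``.  Each of the 19 one-year bins carries the printed sample
    size, mean and SD.
    """
    key = (analyte, sex)
    if key not in _TABLE1:
        raise ValueError(
            f"unknown combination {key}; analyte must be one of {ANALYTES} "
            f"and sex one of {SEXES}")
    bins = [AgeBin(float(k + 1), float(k + 2), n, mean, sd)
            for k, (n, mean, sd) in enumerate(_TABLE1[key])]
    return CohortSpec(analyte=analyte, sex=sex, bins=bins, shape=shape)


def _rescale_counts(bins, n_total):
    counts = np.array([b.n for b in bins], float)
    if n_total < 2 * len(bins):
        raise ValueError(
            f"n_total={n_total} too small for {len(bins)} bins "
            "(need at least 2 per bin)")
    scaled = np.maximum(2, np.rint(counts * n_total / counts.sum()))
    return scaled.astype(int)


def generate_cohort(spec: CohortSpec, n_total: int | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic cohort from per-bin moments.

    Ages are uniform within each bin.  Values follow the bin's (mean, sd)
    under the spec's shape: a Gaussian truncated at ``value_floor``, or a
    moment-matched lognormal (useful for exercising the Box-Cox branch of
    the cleaning stage).  Identical (spec, n_total, seed) give identical
    tables.
    """
    rng = np.random.default_rng(seed)
    if n_total is None:
        counts = [b.n for b in spec.bins]
    else:
        counts = _rescale_counts(spec.bins, n_total)
    ages, values = [], []
    for b, n in zip(spec.bins, counts):
        ages.append(rng.uniform(b.age_lo, b.age_hi, n))
        if spec.shape == "gaussian":
            a = (spec.value_floor - b.mean) / b.sd
            v = stats.truncnorm.rvs(a, np.inf, loc=b.mean, scale=b.sd,
                                    size=n, random_state=rng)
        else:
            s2 = np.log1p((b.sd / b.mean) ** 2)
            v = rng.lognormal(np.log(b.mean) - 0.5 * s2, np.sqrt(s2), n)
            v = np.maximum(v, spec.value_floor)
        values.append(v)
    df = pd.DataFrame({
        "age": np.concatenate(ages),
        "sex": spec.sex,
        "value": np.concatenate(values),
    })
    df.attrs["analyte"] = spec.analyte
    return df


def generate_from_truth(truth: LSSTruth, n: int, seed: int = 0,
                        sex: str = "boy") -> pd.DataFrame:
    """Draw ``n`` subjects from a Box-Cox normal with known L/M/S curves.

    Ages are uniform on ``truth.age_range``; each value is a Box-Cox
    normal draw at the subject's age (z restricted to the family's
    positive domain, a correction with negligible mass for realistic S).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*truth.age_range, n)
    nu, mu, sigma = truth.params_at(ages)
    lim = 1.0 / (sigma * np.maximum(np.abs(nu), 1e-300))
    mass = stats.norm.cdf(lim)
    u = rng.uniform(size=n)
    # truncated standard normal consistent with 1 + nu*sigma*z > 0
    p = np.where(nu > 0, (1.0 - mass) + u * mass,
                 np.where(nu < 0, u * mass, u))
    z = stats.norm.ppf(np.clip(p, 1e-15, 1 - 1e-15))
    values = families.bc_inverse(z, mu, sigma, nu)
    df = pd.DataFrame({"age": ages, "sex": sex, "value": values})
    df.attrs["analyte"] = "synthetic"
    return df


# ---------------------------------------------------------------------------
# cohort table IO
# ---------------------------------------------------------------------------


def validate_samples(df: pd.DataFrame, drop_incomplete: bool = True
                     ) -> pd.DataFrame:
    """Validate an (age, sex, value) table; drop or reject incomplete rows.

    A record is incomplete when age, sex or the analyte value is missing;
    such records are excluded at ingest.  Non-positive values and ages
    outside [1, 20) are rejected outright.
    """
    required = {"age", "sex", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    out = df.loc[:, ["age", "sex", "value"]].copy()
    out["age"] = pd.to_numeric(out["age"], errors="coerce")
    out["value"] = pd.to_numeric(out["value"], errors="coerce")
    incomplete = out["age"].isna() | out["value"].isna() | out["sex"].isna()
    if incomplete.any():
        if not drop_incomplete:
            raise ValueError(f"{int(incomplete.sum())} incomplete records")
        out = out.loc[~incomplete]
    if len(out) == 0:
        raise ValueError("no complete records")
    if (out["value"] <= 0).any():
        raise ValueError("analyte values must be positive")
    bad_sex = ~out["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValueError(f"unknown sex labels: {sorted(out.loc[bad_sex, 'sex'].unique())}")
    return out.reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort as CSV with header ``age,sex,value``."""
    out = df.loc[:, ["age", "sex", "value"]].copy()
    out["age"] = out["age"].map(lambda a: f"{a:.6f}")
    out.to_csv(path, index=False)


def read_cohort(path, drop_incomplete: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV (columns age, sex, value)."""
    return validate_samples(pd.read_csv(path), drop_incomplete=drop_incomplete)
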