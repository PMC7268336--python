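"""Time-frame construction, bootstrap limits, and the non-parametric RI."""

import numpy as np
import pandas as pd
import pytest

import refcurve as rc
from refcurve.nonparametric import (FrameConfig, bootstrap_limits,
                                    build_time_frames, discrete_limits)


def _table(n, seed=0, lo=1.0, hi=19.0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({"age": rng.uniform(lo, hi, n), "sex": "boy",
                         "value": rng.normal(100, 10, n)})


class TestFrameConstruction:
    def test_single_frame(self):
        df = _table(120)
        frames = build_time_frames(df, FrameConfig(n=120, m=7))
        assert len(frames) == 1
        assert frames[0].values.size == 120

    def test_stride_count_example(self):
        df = _table(124)
        frames = build_time_frames(df, FrameConfig(n=120, m=2))
        assert len(frames) == 3  # starts 0, 2, 4

    def test_undersized_table_rejected(self):
        with pytest.raises(ValueError, match="below one frame"):
            build_time_frames(_table(119), FrameConfig(n=120, m=2))

    @pytest.mark.parametrize("N,n,m", [(500, 120, 2), (501, 120, 7),
                                       (1000, 60, 60), (261, 30, 13)])
    def test_count_matches_formula(self, N, n, m):
        frames = build_time_frames(_table(N), FrameConfig(n=n, m=m))
        base = (N - n) // m + 1
        extra = 0 if (N - n) % m == 0 else 1  # trailing window
        assert len(frames) == base + extra
        assert frames[-1].indices.size == n

    def test_frames_cover_and_means_monotone(self):
        df = _table(487)
        cfg = FrameConfig(n=60, m=9)
        frames = build_time_frames(df, cfg)
        covered = np.zeros(len(df), bool)
        means = []
        for f in frames:
            covered[f.indices] = True
            means.append(f.mean_age)
        assert covered.all()          # every record in >= 1 frame (m <= n)
        assert np.all(np.diff(means) >= 0)

    def test_frames_are_age_consecutive(self):
        df = _table(300)
        frames = build_time_frames(df, FrameConfig(n=50, m=25))
        ages = np.sort(df["age"].to_numpy())
        for i, f in enumerate(frames[:-1]):
            np.testing.assert_allclose(
                np.sort(df["age"].to_numpy()[f.indices]),
                ages[i * 25:i * 25 + 50])


class TestBootstrapLimits:
    def test_degenerate_frame(self):
        df = pd.DataFrame({"age": np.linspace(1, 2, 120), "sex": "boy",
                           "value": 7.0})
        cfg = FrameConfig()
        frame = build_time_frames(df, cfg)[0]
        lim = bootstrap_limits(frame, cfg, seed=0)
        assert lim.lower == lim.upper == 7.0
        assert lim.bootstrap_se == (0.0, 0.0)
        assert lim.degenerate

    def test_large_B_median_converges(self):
        df = pd.DataFrame({"age": np.linspace(1, 2, 120), "sex": "boy",
                           "value": np.arange(1.0, 121.0)})
        cfg = FrameConfig(bootstrap_B=4000, percentiles=(0.5, 0.975))
        frame = build_time_frames(df, cfg)[0]
        lim = bootstrap_limits(frame, cfg, seed=1)
        # bootstrap mean of the sample median -> the empirical median 60.5
        assert lim.lower == pytest.approx(60.5, abs=1.0)

    def test_determinism(self):
        cfg = FrameConfig()
        frame = build_time_frames(_table(150), cfg)[0]
        a = bootstrap_limits(frame, cfg, seed=3)
        b = bootstrap_limits(frame, cfg, seed=3)
        assert (a.lower, a.upper, a.bootstrap_se) == \
            (b.lower, b.upper, b.bootstrap_se)

    def test_linear_transform_equivariance(self):
        """Bootstrap limits commute exactly with increasing affine maps."""
        cfg = FrameConfig(bootstrap_B=300)
        df = _table(150, seed=5)
        frame = build_time_frames(df, cfg)[0]
        a = bootstrap_limits(frame, cfg, seed=7)
        df2 = df.assign(value=3.0 * df["value"] + 11.0)
        frame2 = build_time_frames(df2, cfg)[0]
        b = bootstrap_limits(frame2, cfg, seed=7)
        assert b.lower == pytest.approx(3 * a.lower + 11.0)
        assert b.upper == pytest.approx(3 * a.upper + 11.0)

    def test_partition_equals_groupwise_bootstrap(self):
        """With m = n frames partition the data; limits must equal a plain
        per-group bootstrap written out independently."""
        df = _table(360, seed=8)
        cfg = FrameConfig(n=120, m=120, bootstrap_B=200)
        lims = discrete_limits(df, cfg, seed=9)
        ages = np.sort(df["age"].to_numpy())
        order = np.argsort(df["age"].to_numpy(), kind="stable")
        vals = df["value"].to_numpy()[order]
        children = np.random.SeedSequence(9).spawn(3)
        for k, (lim, ss) in enumerate(zip(lims, children)):
            group = vals[k * 120:(k + 1) * 120]
            rng = np.random.default_rng(ss)
            qs = []
            for _ in range(200):
                res = group[rng.integers(0, 120, 120)]
                qs.append(np.quantile(res, [0.025, 0.975]))
            qs = np.array(qs)
            assert lim.lower == pytest.approx(qs[:, 0].mean(), abs=1e-9)
            assert lim.upper == pytest.approx(qs[:, 1].mean(), abs=1e-9)


class TestNonparametricFit:
    def test_age_independent_gaussian(self, flat_gaussian):
        # stiff basis: overlapping frames make the limit series strongly
        # autocorrelated, so automatic selection undersmooths
        ri = rc.nonparametric_fit(flat_gaussian, FrameConfig(n=120, m=10),
                                  smoother_params={"basis_size": 8}, seed=0)
        grid = np.linspace(3, 17, 20)
        # per-frame limit SE is ~2.4 (percentile of 120 draws); after
        # smoothing the pointwise SE is ~1.7, so allow ~2.4 SEs over grid
        assert np.allclose(ri.lower(grid), 100 - 1.96 * 10, atol=4.0)
        assert np.allclose(ri.upper(grid), 100 + 1.96 * 10, atol=4.0)

    def test_recovers_truth_curves(self, smooth_truth, truth_cohort):
        ri = rc.nonparametric_fit(truth_cohort, FrameConfig(n=120, m=5),
                                  smoother_params={"basis_size": 10}, seed=1)
        lo, hi = smooth_truth.age_range
        span = hi - lo
        grid = np.linspace(lo + 0.1 * span, hi - 0.1 * span, 40)
        for curve, p in ((ri.lower, 0.025), (ri.upper, 0.975)):
            truth_q = smooth_truth.quantile(p, grid)
            rel = np.abs(curve(grid) / truth_q - 1.0)
            assert np.max(rel) < 0.05

    def test_alp_shape_peak_then_crash(self, cleaned_alp_boy):
        """ALP upper limit peaks around puberty then falls steeply."""
        ri = rc.nonparametric_fit(cleaned_alp_boy, FrameConfig(n=120, m=4),
                                  seed=2)
        grid = np.linspace(1.5, 19.0, 100)
        up = ri.upper(grid)
        peak_age = grid[np.argmax(up)]
        assert 9.0 <= peak_age <= 15.0
        assert up[-1] < 0.5 * up.max()   # cliff-like descent by age 19

    def test_mixed_sex_rejected(self, flat_gaussian):
        df = flat_gaussian.copy()
        df.loc[:10, "sex"] = "girl"
        with pytest.raises(ValueError, match="one sex"):
            rc.nonparametric_fit(df, FrameConfig(n=60, m=30), seed=0)


class TestFrameConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"n": 10}, {"m": 0}, {"n": 50, "m": 60}, {"bootstrap_B": 10},
        {"percentiles": (0.9, 0.1)},
    ])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            FrameConfig(**kw)
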