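"""Train/test splitting, out-of-range scoring, baselines, comparisons."""

import numpy as np
import pandas as pd
import pytest

import refcurve as rc
from refcurve.curves import ContinuousRI, QuantileCurve
from refcurve.validation import discrete_baseline, oor, run_comparison, split


def _cohort(n=1000, seed=0, sexes=("boy", "girl")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "age": rng.uniform(1, 19, n),
        "sex": rng.choice(sexes, n),
        "value": rng.normal(100, 10, n),
    })


def _const_ri(lo, hi, domain=(1.0, 19.0)):
    return ContinuousRI(
        lower=QuantileCurve(0.025, lambda t: np.full_like(t, lo, dtype=float),
                            domain, "stepwise"),
        upper=QuantileCurve(0.975, lambda t: np.full_like(t, hi, dtype=float),
                            domain, "stepwise"),
        method="const")


class TestSplit:
    def test_ratio_per_sex(self):
        df = _cohort(1000, seed=1)
        sp = split(df, seed=0)
        for sex in ("boy", "girl"):
            n_tr = (sp.train["sex"] == sex).sum()
            n_te = (sp.test["sex"] == sex).sum()
            assert abs(n_tr - 0.8 * (n_tr + n_te)) <= 1

    def test_disjoint_union(self):
        df = _cohort(500, seed=2)
        sp = split(df, seed=3)
        assert len(sp.train) + len(sp.test) == len(df)
        merged = pd.concat([sp.train, sp.test]).sort_values(
            ["age", "value"]).reset_index(drop=True)
        orig = df.sort_values(["age", "value"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, orig)

    def test_determinism(self):
        df = _cohort(400, seed=4)
        s1, s2 = split(df, seed=5), split(df, seed=5)
        pd.testing.assert_frame_equal(s1.train, s2.train)
        assert s1.wilcoxon_p == s2.wilcoxon_p

    def test_wilcoxon_acceptance_is_reported(self):
        df = _cohort(600, seed=6)
        sp = split(df, seed=7)
        assert sp.wilcoxon_p >= 0.05
        assert sp.attempts >= 1

    def test_null_first_attempt_rate(self):
        """Under identical age distributions the check rejects at ~alpha."""
        df = _cohort(300, seed=8, sexes=("boy",))
        first = sum(split(df, seed=s).attempts == 1 for s in range(200))
        assert first >= 180  # ~95% expected, binomial slack

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 50"):
            split(_cohort(60, seed=9), seed=0)


class TestOOR:
    def test_direct_count_example(self):
        test = pd.DataFrame({"age": [2.0, 5.0, 9.0, 14.0], "sex": "boy",
                             "value": [-1.0, 5.0, 11.0, 12.0]})
        res = oor(_const_ri(0.0, 10.0), test)
        assert res.total_pct == 75.0
        assert res.lower_pct == 25.0
        assert res.upper_pct == 50.0

    def test_all_inside(self):
        test = pd.DataFrame({"age": [3.0, 4.0], "sex": "boy",
                             "value": [5.0, 6.0]})
        res = oor(_const_ri(0.0, 10.0), test)
        assert (res.total_pct, res.lower_pct, res.upper_pct) == (0, 0, 0)

    def test_matches_per_record_loop(self):
        rng = np.random.default_rng(10)
        test = pd.DataFrame({"age": rng.uniform(1, 19, 500), "sex": "boy",
                             "value": rng.normal(100, 25, 500)})
        ri = _const_ri(70.0, 130.0)
        res = oor(ri, test)
        below = above = 0
        for _, row in test.iterrows():   # independent brute-force oracle
            if row.value < ri.lower(row.age):
                below += 1
            elif row.value > ri.upper(row.age):
                above += 1
        assert res.lower_pct == pytest.approx(100 * below / 500)
        assert res.upper_pct == pytest.approx(100 * above / 500)
        assert res.total_pct == pytest.approx(res.lower_pct + res.upper_pct)

    def test_shuffle_invariance_and_additivity(self):
        rng = np.random.default_rng(11)
        test = pd.DataFrame({"age": rng.uniform(1, 19, 400), "sex": "boy",
                             "value": rng.normal(100, 20, 400)})
        ri = _const_ri(75.0, 125.0)
        base = oor(ri, test)
        shuffled = oor(ri, test.sample(frac=1, random_state=1))
        assert shuffled.total_pct == base.total_pct
        a, b = test.iloc[:150], test.iloc[150:]
        ra, rb = oor(ri, a), oor(ri, b)
        pooled = (len(a) * ra.total_pct + len(b) * rb.total_pct) / len(test)
        assert pooled == pytest.approx(base.total_pct)

    def test_per_age_counts_reconcile(self):
        rng = np.random.default_rng(12)
        test = pd.DataFrame({"age": rng.uniform(1, 19, 300), "sex": "boy",
                             "value": rng.normal(100, 20, 300)})
        res = oor(_const_ri(80.0, 120.0), test)
        assert res.per_age["n"].sum() == res.n_test
        weighted = (res.per_age["total_pct"] * res.per_age["n"]).sum() / 300
        assert weighted == pytest.approx(res.total_pct)

    def test_empty_test_rejected(self):
        with pytest.raises(ValueError):
            oor(_const_ri(0, 1), pd.DataFrame(columns=["age", "sex",
                                                       "value"]))


class TestDiscreteBaseline:
    def test_age_independent_steps_match_pooled_quantiles(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"age": rng.uniform(1, 19, 6000), "sex": "boy",
                           "value": rng.normal(100, 10, 6000)})
        ri = discrete_baseline(df, bin_years=3.0)
        pooled = np.quantile(df["value"], [0.025, 0.975])
        grid = np.linspace(2, 18, 30)
        assert np.allclose(ri.lower(grid), pooled[0], atol=2.0)
        assert np.allclose(ri.upper(grid), pooled[1], atol=2.0)

    def test_single_bin_constant(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame({"age": rng.uniform(1, 19, 500), "sex": "boy",
                           "value": rng.normal(50, 5, 500)})
        ri = discrete_baseline(df, bin_years=25.0)
        grid = np.linspace(2, 18, 10)
        assert np.ptp(ri.lower(grid)) == 0.0
        assert ri.lower(5.0) == pytest.approx(np.quantile(df["value"], 0.025))

    def test_steps_jump_at_edges_on_trend_data(self):
        """Discrete limits form a ladder on trending data while a
        continuous fit moves smoothly through bin boundaries."""
        rng = np.random.default_rng(15)
        t = rng.uniform(1, 19, 8000)
        df = pd.DataFrame({"age": t, "sex": "boy",
                           "value": 5.0 * t + rng.normal(0, 3.0, 8000)})
        ri = discrete_baseline(df, bin_years=3.0)
        eps = 1e-6
        jump = abs(float(ri.upper(7.0 + eps) - ri.upper(7.0 - eps)))
        assert jump > 5.0  # ~bin_years * slope
        cont = rc.rs_fit(df)
        smooth_jump = abs(float(cont.upper(7.0 + eps) - cont.upper(7.0 - eps)))
        assert smooth_jump < 0.1


class TestRunComparison:
    def _methods(self):
        return {"const": lambda train, seed: _const_ri(
            np.quantile(train["value"], 0.025),
            np.quantile(train["value"], 0.975))}

    def test_single_rep_equals_single_oor(self):
        df = _cohort(800, seed=16)
        rep = run_comparison(df, self._methods(), repetitions=1, base_seed=2)
        sp = split(df, seed=2)
        m = self._methods()["const"]
        single = oor(m(sp.train, 2), sp.test)
        row = rep.table.iloc[0]
        assert row["total_mean"] == pytest.approx(single.total_pct)
        assert row["total_sd"] == 0.0

    def test_identical_methods_identical_rows(self):
        df = _cohort(800, seed=17)
        m = self._methods()["const"]
        rep = run_comparison(df, {"a": m, "b": m}, repetitions=3, base_seed=0)
        ra = rep.table[rep.table.method == "a"].drop(columns="method")
        rb = rep.table[rep.table.method == "b"].drop(columns="method")
        assert ra.reset_index(drop=True).equals(rb.reset_index(drop=True))

    def test_reproducible_end_to_end(self):
        df = _cohort(800, seed=18)
        r1 = run_comparison(df, self._methods(), repetitions=3, base_seed=5)
        r2 = run_comparison(df, self._methods(), repetitions=3, base_seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_failing_method_reported_not_fatal(self):
        df = _cohort(800, seed=19)

        def bad(train, seed):
            raise RuntimeError("boom")

        methods = dict(self._methods(), bad=bad)
        rep = run_comparison(df, methods, repetitions=2, base_seed=0)
        bad_row = rep.table[rep.table.method == "bad"].iloc[0]
        assert bool(bad_row["failed"])
        assert np.isnan(bad_row["total_mean"])
        good = rep.table[rep.table.method == "const"].iloc[0]
        assert np.isfinite(good["total_mean"])
        assert rep.valid("const")
        assert not rep.valid("bad")
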