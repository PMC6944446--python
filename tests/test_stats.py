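import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gcfate import stats as st


class TestSpearman:
    def test_perfect_monotone(self):
        assert st.spearman([1, 2, 3], [2, 4, 6]).rs == 1.0
        assert st.spearman([1, 2, 3], [6, 4, 2]).rs == -1.0

    def test_rank_invariance(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        direct = st.spearman(x, y).rs
        ranked = st.spearman(sps.rankdata(x), sps.rankdata(y)).rs
        assert direct == pytest.approx(ranked, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=80), rng.normal(size=80)
        assert st.spearman(np.exp(x), y).rs == pytest.approx(
            st.spearman(x, y).rs, abs=1e-12)

    def test_pairwise_deletion_counts_complete_cases(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, np.nan, 3, 8, 10]
        assert st.spearman(x, y).n == 3

    def test_constant_vector_warns_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            res = st.spearman([1, 1, 1], [1, 2, 3])
        assert math.isnan(res.rs)


class TestPartialSpearman:
    def test_full_confounding_zeroes_out(self, rng):
        x = rng.normal(size=100)
        y = x + rng.normal(size=100) * 0.1
        with pytest.warns(UserWarning, match="fully explained"):
            res = st.partial_spearman(x, y, {"z": x})
        assert abs(res.rs) < 1e-6

    def test_empty_controls_equals_plain(self, rng):
        x, y = rng.normal(size=60), rng.normal(size=60)
        assert st.partial_spearman(x, y, {}).rs == st.spearman(x, y).rs

    def test_conditional_independence_recovered(self, rng):
        """x and y both driven by z but conditionally independent: the
        partial correlation given z vanishes (generative ground truth)."""
        n = 5000
        z = rng.normal(size=n)
        x = 0.8 * z + rng.normal(size=n) * 0.6
        y = -0.7 * z + rng.normal(size=n) * 0.7
        plain = st.spearman(x, y).rs
        part = st.partial_spearman(x, y, {"z": z}).rs
        assert abs(plain) > 0.3
        assert abs(part) < 0.05

    def test_independent_control_changes_little(self, rng):
        n = 5000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        w = rng.normal(size=n)  # independent of both
        assert st.partial_spearman(x, y, {"w": w}).rs == pytest.approx(
            st.spearman(x, y).rs, abs=0.02)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 300
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = z + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        expected = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                         method="spearman")
        got = st.partial_spearman(x, y, {"z": z})
        assert got.rs == pytest.approx(float(expected["r"].iloc[0]), abs=1e-9)

    def test_collinear_controls_raise(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        with pytest.raises(ValueError, match="singular|collinear"):
            st.partial_spearman(x, y, {"a": x, "b": x})


class TestMengComparison:
    def test_equal_correlations_give_zero(self):
        z, p = st.compare_dependent_correlations(0.5, 0.5, 0.3, 100)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        z1, _ = st.compare_dependent_correlations(0.6, 0.2, 0.3, 80)
        z2, _ = st.compare_dependent_correlations(0.2, 0.6, 0.3, 80)
        assert z1 == pytest.approx(-z2)

    def test_degenerate_r_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            st.compare_dependent_correlations(1.0, 0.5, 0.3, 50)

    def test_matches_permutation_oracle(self, rng):
        """Under a true null (rho_xy == rho_xz, exchangeable y/z), the Meng
        p agrees with a row-swap permutation test within Monte-Carlo error."""
        n, n_perm = 500, 2000
        cov = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.3], [0.4, 0.3, 1.0]])
        data = rng.multivariate_normal(np.zeros(3), cov, size=n)
        x, y, z = data.T

        def stat(yv, zv):
            return (sps.spearmanr(x, yv).statistic
                    - sps.spearmanr(x, zv).statistic)

        observed = stat(y, z)
        count = 0
        for _ in range(n_perm):
            swap = rng.random(n) < 0.5
            y2 = np.where(swap, z, y)
            z2 = np.where(swap, y, z)
            if abs(stat(y2, z2)) >= abs(observed):
                count += 1
        p_perm = count / n_perm
        r_xy = sps.spearmanr(x, y).statistic
        r_xz = sps.spearmanr(x, z).statistic
        r_yz = sps.spearmanr(y, z).statistic
        _, p_meng = st.compare_dependent_correlations(r_xy, r_xz, r_yz, n)
        mc_err = 3 * math.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm)
        assert p_meng == pytest.approx(p_perm, abs=max(0.05, mc_err))


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = st.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-9)  # exact two-sided 2/C(6,3)

    def test_identical_samples(self):
        _, p = st.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(100):
            a = rng.integers(0, 10, size=rng.integers(3, 15)).astype(float)
            b = rng.integers(0, 10, size=rng.integers(3, 15)).astype(float)
            u, _ = st.mann_whitney(a, b)
            brute = sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)
            assert u == pytest.approx(brute)


class TestClassSchemes:
    def test_boundary_goes_left_closed(self):
        scheme = st.gc_classes()
        labels = st.assign_classes([0.40, 0.39, 0.61], scheme)
        assert list(labels) == ["40-45%", "<40%", ">60%"]

    def test_partition_conserves_n(self, rng):
        scheme = st.length_classes()
        vals = pd.Series(rng.uniform(100, 20000, size=500))
        vals.iloc[:17] = np.nan
        labels = st.assign_classes(vals, scheme)
        assert labels.value_counts().sum() == 500 - 17

    def test_invalid_breakpoints_raise(self):
        with pytest.raises(ValueError, match="increasing"):
            st.ClassScheme("bad", (2.0, 1.0), ("a", "b", "c"))

    def test_eight_gc3_classes(self):
        assert len(st.gc3_classes().labels) == 8


class TestFixedWidthHistogram:
    def test_uniform_ten_bins(self, rng):
        vals = rng.uniform(0.4, 0.4999, size=100)
        hist = st.fixed_width_histogram(vals, width=0.01)
        assert hist["count"].sum() == 100
        assert len(hist) == 10

    def test_subgroup_counts_sum_to_total(self, rng):
        vals = pd.Series(rng.uniform(0.3, 0.7, size=400))
        groups = pd.Series(rng.choice(["PB-in", "PB-out"], size=400))
        hist = st.fixed_width_histogram(vals, groups=groups)
        assert (hist["count_PB-in"] + hist["count_PB-out"]
                == hist["count"]).all()

    def test_recovers_generative_median_shift(self, rng):
        """PB-in synthesized 8 GC points below PB-out: the reported group
        medians differ by 8 +/- 0.5 points."""
        n = 5000
        pb_in = rng.normal(0.42, 0.04, size=n)
        pb_out = rng.normal(0.50, 0.04, size=n)
        vals = pd.Series(np.concatenate([pb_in, pb_out]))
        groups = pd.Series(["PB-in"] * n + ["PB-out"] * n)
        hist = st.fixed_width_histogram(vals, width=0.007, groups=groups)
        med = hist.attrs["medians"]
        assert (med["PB-out"] - med["PB-in"]) * 100 == pytest.approx(8, abs=0.5)


class TestEqualCountTendency:
    def test_diagonal(self):
        x = np.arange(1000, dtype=float)
        curve = st.equal_count_tendency(x, x, bin_size=500)
        assert len(curve) == 2
        assert np.allclose(curve["x_median"], curve["y_median"])

    def test_monotone_trend_preserved(self, rng):
        x = rng.uniform(0, 1, size=2000)
        y = x ** 2 + rng.normal(scale=0.01, size=2000)
        curve = st.equal_count_tendency(x, y, bin_size=400)
        assert curve["y_median"].is_monotonic_increasing

    def test_small_n_single_bin_warns(self, rng):
        with pytest.warns(UserWarning, match="single bin"):
            curve = st.equal_count_tendency(rng.normal(size=50),
                                            rng.normal(size=50), bin_size=500)
        assert len(curve) == 1

    def test_short_tail_merged(self):
        x = np.arange(1100, dtype=float)
        curve = st.equal_count_tendency(x, x, bin_size=500)
        assert list(curve["n"]) == [500, 600]


class TestStratifiedDistribution:
    def test_identical_groups_identical_summaries(self, rng):
        df = pd.DataFrame({"gc3": rng.uniform(0.3, 0.8, 200),
                           "v": rng.normal(size=200)})
        df = pd.concat([df.assign(g="a"), df.assign(g="b")])
        out = st.stratified_distribution(df, "gc3", st.gc3_classes(), "v", "g")
        a = out[out.group == "a"].drop(columns="group").reset_index(drop=True)
        b = out[out.group == "b"].drop(columns="group").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_linear_interpolation_quartiles(self):
        df = pd.DataFrame({"x": np.full(100, 0.5),
                           "v": np.arange(1, 101, dtype=float),
                           "g": "all"})
        out = st.stratified_distribution(df, "x", st.gc_classes(), "v", "g")
        row = out[out.n > 0].iloc[0]
        assert (row.p25, row.p50, row.p75) == (25.75, 50.5, 75.25)

    def test_total_n_conserved_and_empty_reported(self, rng):
        df = pd.DataFrame({"x": rng.uniform(0.41, 0.44, 300),
                           "v": rng.normal(size=300), "g": "all"})
        out = st.stratified_distribution(df, "x", st.gc_classes(), "v", "g")
        assert out["n"].sum() == 300
        assert (out["n"] == 0).any()

    def test_recovers_between_group_gap(self, rng):
        """A 10-point GC3 gap built into every stratum is recovered within
        1 point from the per-stratum medians."""
        n = 4000
        strat_gc = rng.uniform(0.30, 0.60, size=n)
        rows = []
        for g, offset in (("PB-in", 0.0), ("PB-out", 0.10)):
            rows.append(pd.DataFrame({
                "gc_utr3": strat_gc,
                "gc3": rng.normal(0.45 + offset, 0.02, size=n), "g": g}))
        df = pd.concat(rows)
        out = st.stratified_distribution(df, "gc_utr3", st.utr3_gc_classes(),
                                         "gc3", "g")
        wide = out.pivot(index="stratum", columns="group", values="p50")
        gaps = (wide["PB-out"] - wide["PB-in"]).dropna() * 100
        assert len(gaps) == 6
        assert np.all(np.abs(gaps - 10) < 1)
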