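"""Statistical primitives against brute-force and hand-computed oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy import stats as sps

from wormepi.stats import (
    bh_fdr,
    blot_ratio,
    fishers_method,
    one_way_anova_tukey,
    rank_sum_test,
    two_way_anova_bonferroni,
    welch_t_test,
)


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([3, 5, 7], [3, 5, 7])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_matches_hand_formula(self):
        # independent scalar evaluation of the Welch t and
        # Welch-Satterthwaite df
        x = np.array([10.0, 12.0, 14.0])
        y = np.array([11.0, 13.0, 15.0, 17.0])
        sx2, sy2 = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t_hand = (x.mean() - y.mean()) / math.sqrt(sx2 + sy2)
        df_hand = (sx2 + sy2) ** 2 / (
            sx2**2 / (x.size - 1) + sy2**2 / (y.size - 1)
        )
        res = welch_t_test(x, y)
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.df == pytest.approx(df_hand, rel=1e-12)
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_hand), df_hand), rel=1e-12)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            welch_t_test([1], [2, 3])

    def test_zero_variance_conventions(self):
        assert welch_t_test([2, 2, 2], [2, 2]).p == 1.0
        assert welch_t_test([2, 2, 2], [3, 3]).p == 0.0

    def test_equals_pooled_t_under_equal_variance_and_size(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        # equal sizes: Welch df differs but the statistic matches pooled t
        t_pooled, _ = sps.ttest_ind(x, y, equal_var=True)
        res = welch_t_test(x, y)
        assert res.statistic == pytest.approx(t_pooled, abs=1e-10)

    def test_symmetry_up_to_sign(self, rng):
        x, y = rng.normal(0, 1, 5), rng.normal(1, 2, 7)
        a, b = welch_t_test(x, y), welch_t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)


class TestAnovaTukey:
    def test_identical_groups(self):
        om, pairs = one_way_anova_tukey({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert om.statistic == 0.0
        assert om.p == 1.0
        assert (pairs["p_adj"] == 1.0).all()

    def test_two_groups_f_equals_t_squared(self, rng):
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 9)
        om, _ = one_way_anova_tukey({"x": x, "y": y})
        t_pooled, _ = sps.ttest_ind(x, y, equal_var=True)
        assert om.statistic == pytest.approx(t_pooled**2, rel=1e-10)

    def test_adjusted_p_not_below_raw(self, rng):
        groups = {k: rng.normal(i * 0.3, 1, 7) for i, k in enumerate("abcd")}
        _, pairs = one_way_anova_tukey(groups)
        for _, row in pairs.iterrows():
            _, p_raw = sps.ttest_ind(
                groups[row["group1"]], groups[row["group2"]], equal_var=True
            )
            assert row["p_adj"] >= p_raw - 1e-12

    @pytest.mark.parametrize("bad", [{"a": [1, 2]}, {"a": [1], "b": [2, 3]}])
    def test_invalid_groups_error(self, bad):
        with pytest.raises(ValueError):
            one_way_anova_tukey(bad)


def _grid_data(rng, n_groups=2, n_bins=6, n_per_cell=5, shift_bins=(), shift=0.0):
    rows = []
    for g in range(n_groups):
        for b in range(n_bins):
            mu = shift if (g == 1 and b in shift_bins) else 0.0
            for v in rng.normal(mu, 1.0, n_per_cell):
                rows.append({"value": v, "group": f"g{g}", "bin": b})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_identical_groups_all_adjusted_one(self, rng):
        vals = rng.normal(0, 1, 30)
        df = pd.DataFrame(
            {
                "value": np.tile(vals, 2),
                "group": ["a"] * 30 + ["b"] * 30,
                "bin": list(range(6)) * 5 + list(range(6)) * 5,
            }
        )
        _, per_bin = two_way_anova_bonferroni(df)
        assert (per_bin["p_adj"] == 1.0).all()

    def test_bonferroni_matches_per_bin_welch_oracle(self, rng):
        df = _grid_data(rng, n_bins=8, shift_bins=(2,), shift=3.0)
        _, per_bin = two_way_anova_bonferroni(df)
        m = df["bin"].nunique()
        for _, row in per_bin.iterrows():
            sub = df[df["bin"] == row["bin"]]
            p_oracle = welch_t_test(
                sub.loc[sub["group"] == "g0", "value"],
                sub.loc[sub["group"] == "g1", "value"],
            ).p
            assert row["p_adj"] == pytest.approx(min(1.0, p_oracle * m), rel=1e-12)

    def test_planted_shift_flags_only_planted_bins(self):
        rng = np.random.default_rng(7)
        planted = {6, 7, 8, 9}
        df = _grid_data(rng, n_bins=20, n_per_cell=12, shift_bins=planted, shift=2.5)
        _, per_bin = two_way_anova_bonferroni(df)
        flagged = set(per_bin.loc[per_bin["significant"], "bin"])
        assert flagged <= planted
        assert len(flagged) >= 3  # strong planted effect is mostly detected

    def test_single_bin_reduces_to_one_way(self, rng):
        df = _grid_data(rng, n_bins=1, n_per_cell=10)
        omnibus, per_bin = two_way_anova_bonferroni(df)
        assert len(per_bin) == 1
        assert per_bin["p_adj"].iloc[0] == pytest.approx(per_bin["p_raw"].iloc[0])

    def test_empty_cell_error_names_cell(self, rng):
        df = _grid_data(rng, n_bins=3)
        df = df[~((df["group"] == "g1") & (df["bin"] == 2))]
        with pytest.raises(ValueError, match="g1"):
            two_way_anova_bonferroni(df)


def _rank_sum_oracle(x, y):
    """Exhaustive two-sided p over all rank assignments (independent code)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    m = len(x)
    mu = ranks.sum() * m / len(pooled)
    w_obs = ranks[:m].sum()
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), m):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestRankSum:
    def test_identical_multisets(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]).p >= 0.99

    def test_disjoint_small_samples_exact(self):
        # one-sided exact p for {1,2,3} vs {4,5,6} is 1/20; the two-sided
        # p doubles it because the null distribution is symmetric
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(2 / 20)

    def test_all_tied(self):
        assert rank_sum_test([5, 5], [5, 5, 5]).p == 1.0

    def test_exact_path_equals_enumeration_exhaustively(self, rng):
        # every split size with m+n <= 8, values drawn with heavy ties
        for m in range(1, 7):
            for n in range(1, 8 - m + 1):
                vals = rng.integers(0, 4, size=m + n).astype(float)
                res = rank_sum_test(vals[:m], vals[m:])
                assert res.p == pytest.approx(_rank_sum_oracle(vals[:m], vals[m:]))

    def test_exact_agrees_with_scipy_when_tie_free(self, rng):
        x = rng.permutation(np.arange(10.0))[:4]
        y = np.setdiff1d(np.arange(10.0), x)
        ours = rank_sum_test(x, y).p
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestFisher:
    def test_all_ones(self):
        res = fishers_method([1, 1, 1])
        assert res.chi2 == 0.0
        assert res.p == 1.0
        assert res.df == 6

    def test_single_p_passthrough(self):
        for p0 in (0.013, 0.2, 0.77):
            assert fishers_method([p0]).p == pytest.approx(p0, rel=1e-12)

    def test_against_quadrature_oracle(self):
        ps = [0.01, 0.04, 0.20]
        res = fishers_method(ps)
        assert res.chi2 == pytest.approx(-2 * np.log(ps).sum(), rel=1e-12)
        # numeric integration of the chi-square(6) density as oracle
        p_oracle, _ = integrate.quad(lambda u: sps.chi2.pdf(u, 6), res.chi2, np.inf)
        assert res.p == pytest.approx(p_oracle, rel=1e-8)

    def test_zero_p_rejected_without_floor(self):
        with pytest.raises(ValueError, match="floor"):
            fishers_method([0.0, 0.5])
        assert fishers_method([0.0, 0.5], floor=1e-300).p < 1e-250

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fishers_method([0.5, 1.2])


def _bh_oracle(ps):
    """Step-up definition: q_(i) = min over j >= i of m * p_(j) / j."""
    ps = np.asarray(ps, float)
    m = ps.size
    order = np.argsort(ps, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(m * ps[order[j]] / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestBhFdr:
    def test_identical_ps(self):
        assert np.allclose(bh_fdr([0.3] * 5), 0.3)

    def test_single_p(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_frozen_example_vs_oracle(self):
        ps = [0.001, 0.008, 0.039, 0.041, 0.042, 0.060, 0.074, 0.205]
        assert np.allclose(bh_fdr(ps), _bh_oracle(ps))

    def test_random_vectors_vs_oracle_and_invariants(self, rng):
        for _ in range(50):
            ps = rng.random(rng.integers(1, 30))
            q = bh_fdr(ps)
            assert np.allclose(q, _bh_oracle(ps))
            assert np.all(q >= ps - 1e-15)
            perm = rng.permutation(ps.size)
            assert np.allclose(bh_fdr(ps[perm]), q[perm])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=20))
def test_bh_fdr_bounds_property(ps):
    """Adjusted values always lie in [p_i, 1] and respect step-up order."""
    q = bh_fdr(ps)
    assert np.all(q >= np.asarray(ps) - 1e-15)
    assert np.all(q <= 1.0)
    order = np.argsort(ps, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=10)
)
def test_fishers_method_df_and_chi2_property(ps):
    """chi2 reproduces -2 sum(ln p) and df is twice the input count."""
    res = fishers_method(ps)
    assert res.df == 2 * len(ps)
    assert res.chi2 == pytest.approx(-2.0 * np.log(ps).sum(), rel=1e-9, abs=1e-9)


class TestBlotRatio:
    def test_ptm_equals_h3(self):
        t = blot_ratio(
            [5, 6, 7, 8], [5, 6, 7, 8], ["tg", "tg", "wt", "wt"], "tg", "wt"
        )
        assert (t.normalized["level"] == 1.0).all()
        assert t.ratio == 1.0

    def test_doubled_treated(self):
        t = blot_ratio(
            [4, 4, 1, 1], [2, 2, 1, 1], ["tg", "tg", "wt", "wt"], "tg", "wt"
        )
        assert t.ratio == pytest.approx(2.0)

    def test_random_table_matches_manual_recomputation(self, rng):
        ptm = rng.uniform(0.5, 5, 8)
        h3 = rng.uniform(0.5, 5, 8)
        cond = np.array(["tg"] * 4 + ["wt"] * 4)
        t = blot_ratio(ptm, h3, cond, "tg", "wt")
        levels = ptm / h3
        assert t.ratio == pytest.approx(levels[:4].mean() / levels[4:].mean())
        assert t.test.p == pytest.approx(
            sps.ttest_ind(levels[:4], levels[4:], equal_var=False).pvalue
        )

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            blot_ratio([1, 0, 1, 1], [1, 1, 1, 1], ["a", "a", "b", "b"], "a", "b")
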