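"""Statistical primitives used throughout the toolkit.

Every test reports its full-precision p-value (never significance stars).
The primitives mirror the analyses common in worm longevity/epigenetics
work: Welch's unequal-variance t-test for pairwise comparisons, one-way
ANOVA with Tukey's HSD for multi-group designs, two-way ANOVA with
per-bin Bonferroni comparisons for group x bin profile data, the
Wilcoxon rank-sum test for per-gene signal distributions, Fisher's
method for combining per-replicate p-values, and Benjamini-Hochberg
FDR for genome-wide multiplicity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "FisherCombined",
    "BlotRatioTable",
    "welch_t_test",
    "one_way_anova_tukey",
    "two_way_anova_bonferroni",
    "rank_sum_test",
    "fishers_method",
    "bh_fdr",
    "blot_ratio",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    df: float | tuple[float, float] | None
    p: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0) and not math.isnan(self.p):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass(frozen=True)
class FisherCombined:
    """Fisher's combined chi-square over k independent p-values."""

    chi2: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")
        if self.df <= 0 or self.df % 2 != 0:
            raise ValueError("df must be a positive even integer (2k)")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided unpaired t-test with Welch's unequal-variance correction.

    Degenerate inputs with zero variance in both samples are resolved by
    convention: equal means give p = 1 (no evidence of any difference),
    unequal means give p = 0 (the difference is noiseless).
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise ValueError("welch_t_test requires >= 2 values per sample")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if xa.mean() == ya.mean():
            return TestResult(0.0, float(xa.size + ya.size - 2), 1.0, "welch_t")
        return TestResult(math.inf, float(xa.size + ya.size - 2), 0.0, "welch_t")
    res = sps.ttest_ind(xa, ya, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), "welch_t")


def one_way_anova_tukey(
    groups: Mapping[str, Sequence[float]],
) -> tuple[TestResult, pd.DataFrame]:
    """Omnibus one-way ANOVA plus Tukey HSD adjusted p for every group pair.

    Returns the F test and a table with columns
    (group1, group2, mean_diff, p_adj).
    """
    if len(groups) < 2:
        raise ValueError("one_way_anova_tukey requires >= 2 groups")
    arrays = {}
    for name, vals in groups.items():
        arr = _as_1d(vals, f"group {name!r}")
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        arrays[str(name)] = arr
    f_stat, f_p = sps.f_oneway(*arrays.values())
    if not math.isfinite(f_stat):  # all values identical everywhere
        f_stat, f_p = 0.0, 1.0
    k = len(arrays)
    n = sum(a.size for a in arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[name] * a.size for name, a in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels)
    pairs = pd.DataFrame(
        {
            "group1": tukey.groupsunique[tukey._multicomp.pairindices[0]],
            "group2": tukey.groupsunique[tukey._multicomp.pairindices[1]],
            "mean_diff": tukey.meandiffs,
            "p_adj": np.clip(tukey.pvalues, 0.0, 1.0),
        }
    )
    omnibus = TestResult(float(f_stat), (float(k - 1), float(n - k)), float(f_p), "anova_f")
    return omnibus, pairs


def two_way_anova_bonferroni(
    data: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    bin_col: str = "bin",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way (group x bin) ANOVA with per-bin Bonferroni-corrected comparisons.

    The omnibus table uses Type II sums of squares (robust to the
    unbalanced cell counts typical of per-cell imaging data). Each bin is
    then tested for a group difference (Welch t for two groups, one-way
    ANOVA otherwise) and the raw p multiplied by the number of bins,
    capped at 1. A significance flag at ``alpha`` mirrors the standard
    per-bin display convention.

    Returns ``(omnibus_table, per_bin_table)``; per-bin columns are
    (bin, p_raw, p_adj, significant).
    """
    df = data[[value, group, bin_col]].copy()
    df.columns = ["value", "group", "bin"]
    groups = df["group"].unique()
    bins = df["bin"].unique()
    if len(groups) < 2:
        raise ValueError("two_way_anova_bonferroni requires >= 2 groups")
    counts = df.groupby(["group", "bin"], sort=False).size()
    for g in groups:
        for b in bins:
            if (g, b) not in counts.index:
                raise ValueError(f"empty cell: group={g!r}, bin={b!r}")

    if len(bins) >= 2:
        model = ols("value ~ C(group) + C(bin) + C(group):C(bin)", data=df).fit()
        omnibus = anova_lm(model, typ=2).rename_axis("term").reset_index()
    else:
        om, _ = one_way_anova_tukey(
            {str(g): df.loc[df["group"] == g, "value"].to_numpy() for g in groups}
        )
        omnibus = pd.DataFrame(
            {"term": ["C(group)"], "F": [om.statistic], "PR(>F)": [om.p]}
        )

    m = len(bins)
    rows = []
    for b in bins:
        sub = df[df["bin"] == b]
        samples = [sub.loc[sub["group"] == g, "value"].to_numpy() for g in groups]
        if len(samples) == 2:
            p_raw = welch_t_test(samples[0], samples[1]).p
        else:
            p_raw = one_way_anova_tukey(
                {str(g): s for g, s in zip(groups, samples)}
            )[0].p
        p_adj = min(1.0, p_raw * m)
        rows.append({"bin": b, "p_raw": p_raw, "p_adj": p_adj, "significant": p_adj < alpha})
    return omnibus, pd.DataFrame(rows)


def _rank_sum_exact_p(ranks: np.ndarray, m: int) -> tuple[float, float]:
    """Exact two-sided p for the rank-sum W by full enumeration.

    Enumerates all C(m+n, m) assignments of the pooled midranks to the
    first sample; correct under ties because midranks are enumerated.
    Returns (W_observed_is_not_used_here, p).
    """
    n_tot = ranks.size
    w_obs = float(ranks[:m].sum())
    mu = ranks.sum() * m / n_tot
    dev = abs(w_obs - mu)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n_tot), m):
        w = ranks[list(comb)].sum()
        if abs(w - mu) >= dev - 1e-12:
            count += 1
        total += 1
    return w_obs, count / total


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 20
) -> TestResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Uses the exact permutation distribution of the rank-sum statistic
    (enumeration over midranks, valid under ties) when
    ``m + n <= exact_limit``; otherwise the normal approximation with
    tie correction.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    m, n = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:m].sum())
    mu = m * (m + n + 1) / 2.0
    if m + n <= exact_limit:
        _, p = _rank_sum_exact_p(ranks, m)
        return TestResult(w, None, float(p), "rank_sum_exact")
    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((m + n) * (m + n - 1))
    var = m * n / 12.0 * ((m + n + 1) - tie_term)
    if var == 0.0:
        return TestResult(w, None, 1.0, "rank_sum_normal")
    z = (w - mu) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(w, None, float(min(1.0, p)), "rank_sum_normal")


def fishers_method(
    ps: Sequence[float], floor: float | None = None
) -> FisherCombined:
    """Combine k independent p-values: chi2 = -2 sum(ln p) ~ chi2(2k).

    A p of exactly 0 is rejected because -2 ln 0 is undefined; pass
    ``floor`` (e.g. 1e-300) to clip tiny p-values explicitly rather
    than silently.
    """
    arr = _as_1d(ps, "ps")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if floor is not None:
        if floor <= 0:
            raise ValueError("floor must be positive")
        arr = np.maximum(arr, floor)
    if np.any(arr == 0):
        raise ValueError(
            "p-value of 0 passed to fishers_method; supply floor= "
            "(e.g. 1e-300) to clip explicitly"
        )
    chi2 = float(-2.0 * np.log(arr).sum())
    df = 2 * arr.size
    p = float(sps.chi2.sf(chi2, df))
    return FisherCombined(chi2, df, p)


def bh_fdr(ps: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = _as_1d(ps, "ps")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return q


@dataclass
class BlotRatioTable:
    """Western-blot quantification: PTM band intensity normalized to total H3.

    ``ratio`` is mean(treated normalized level) / mean(control
    normalized level), the heatmap value of a blot screen.
    """

    analyte: str
    normalized: pd.DataFrame  # columns: condition, replicate, level
    ratio: float
    test: TestResult = field(repr=False)


def blot_ratio(
    ptm: Sequence[float],
    h3: Sequence[float],
    condition: Sequence[str],
    treated: str,
    control: str,
    analyte: str = "PTM",
) -> BlotRatioTable:
    """Per-lane PTM/H3 normalized levels, condition ratio, and Welch test."""
    p = _as_1d(ptm, "ptm")
    h = _as_1d(h3, "h3")
    cond = np.asarray(condition, dtype=object)
    if not (p.size == h.size == cond.size):
        raise ValueError("ptm, h3 and condition must have matching lengths")
    if np.any(p <= 0) or np.any(h <= 0):
        raise ValueError("band intensities must be strictly positive")
    levels = p / h
    table = pd.DataFrame(
        {"condition": cond, "replicate": np.arange(p.size), "level": levels}
    )
    lv_t = levels[cond == treated]
    lv_c = levels[cond == control]
    if lv_t.size < 2 or lv_c.size < 2:
        raise ValueError("each condition needs >= 2 replicates")
    ratio = float(lv_t.mean() / lv_c.mean())
    test = welch_t_test(lv_t, lv_c)
    return BlotRatioTable(analyte=analyte, normalized=table, ratio=ratio, test=test)
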