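"""Inferential statistics applied to stage outputs.

Thin, validated wrappers around scipy: Pearson χ² on contingency tables
(no continuity correction), one-way ANOVA with Tukey HSD, Wilcoxon rank-sum
(exact null for small samples, normal approximation with tie correction
otherwise), and the paired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

__all__ = ["ContingencyTable", "TestResult", "chi_square",
           "one_way_anova_tukey", "wilcoxon_rank_sum", "paired_t"]


@dataclass
class ContingencyTable:
    counts: np.ndarray
    group_labels: list[str]
    category_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(int)


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    method: str
    summaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def chi_square(table: ContingencyTable) -> TestResult:
    """Pearson χ² with expected counts from row/column margins,
    df = (r−1)(c−1), no continuity correction."""
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table needs >= 2 rows and columns")
    rows, cols = counts.sum(axis=1), counts.sum(axis=0)
    if np.any(rows == 0):
        bad = table.group_labels[int(np.argmin(rows))]
        raise ValueError(f"zero margin for group {bad!r}")
    if np.any(cols == 0):
        bad = table.category_labels[int(np.argmin(cols))]
        raise ValueError(f"zero margin for category {bad!r}")
    stat, p, df, expected = spstats.chi2_contingency(counts, correction=False)
    if np.any(expected < 5):
        warnings.warn(f"{int(np.sum(expected < 5))} cells have expected "
                      "count < 5; χ² approximation may be inaccurate")
    return TestResult(float(stat), int(df), float(p), "Pearson chi-square",
                      {"expected": expected})


def one_way_anova_tukey(groups: list[np.ndarray],
                        labels: list[str] | None = None) -> TestResult:
    """One-way ANOVA F-test plus post-hoc Tukey HSD for every pair."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    labels = labels or [f"g{i}" for i in range(len(groups))]
    if np.concatenate(groups).std() == 0:
        raise ValueError("all values identical: ANOVA undefined")
    f, p = spstats.f_oneway(*groups)
    tk = spstats.tukey_hsd(*groups)
    pairs = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pairs[(labels[i], labels[j])] = {
                "diff": float(groups[i].mean() - groups[j].mean()),
                "p_adj": float(tk.pvalue[i, j]),
                "stat": float(tk.statistic[i, j]),
            }
    k = len(groups)
    n = sum(g.size for g in groups)
    return TestResult(float(f), (k - 1, n - k), float(p),
                      "one-way ANOVA + Tukey HSD", {"tukey": pairs})


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray,
                      alternative: str = "two-sided") -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney).

    Exact null distribution when both samples have n <= 10 and no ties;
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    exact = a.size <= 10 and b.size <= 10 and not has_ties
    res = spstats.mannwhitneyu(a, b, alternative=alternative,
                               method="exact" if exact else "asymptotic",
                               use_continuity=False)
    w = float(res.statistic + a.size * (a.size + 1) / 2)   # rank-sum of a
    return TestResult(w, None, float(res.pvalue),
                      "Wilcoxon rank sum (exact)" if exact
                      else "Wilcoxon rank sum (normal approx.)",
                      {"U": float(res.statistic), "n": (a.size, b.size)})


def paired_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided paired t-test on the differences, df = n − 1."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal-length samples with n >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance differences: t undefined")
    t, p = spstats.ttest_rel(a, b)
    return TestResult(float(t), a.size - 1, float(p), "paired t-test",
                      {"mean_diff": float(d.mean())})
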