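"""Group summaries and nonparametric comparisons.

Summaries follow the median \\ 25th-75th-percentile style, with box-plot
whiskers at Q1 - 1.5 IQR and Q3 + 1.5 IQR.  Comparisons use the Wilcoxon
rank-sum test (unpaired; exact null when both groups have n <= 10 and no
ties, normal approximation with tie correction otherwise) and the Wilcoxon
signed-rank test (paired), two-sided, with significance stars at
0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupSummary", "summarize", "compare_groups", "stars"]


@dataclass
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    mean: float
    sem: float

    def __str__(self) -> str:
        return f"{self.median:.2f}\\{self.q1:.2f}-{self.q3:.2f} (n={self.n})"


def summarize(values) -> GroupSummary:
    """Median, quartiles, whiskers, mean and SEM of a sample."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    return GroupSummary(
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(q1 - 1.5 * iqr),
        whisker_hi=float(q3 + 1.5 * iqr),
        mean=float(v.mean()),
        sem=float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0,
    )


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(a, b, paired: bool = False):
    """Two-sided rank-based comparison of two groups.

    Returns ``(statistic, p, stars)``.  Unpaired uses the Wilcoxon rank-sum
    (Mann-Whitney) test; paired uses the Wilcoxon signed-rank test and
    requires equal lengths.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length groups")
        if a.size < 3:
            raise ValueError("need >= 3 pairs")
        res = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        if a.size < 3 or b.size < 3:
            raise ValueError("need >= 3 values per group")
        pooled = np.concatenate([a, b])
        exact = a.size <= 10 and b.size <= 10 and np.unique(pooled).size == pooled.size
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
    p = float(res.pvalue)
    return float(res.statistic), p, stars(p)
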