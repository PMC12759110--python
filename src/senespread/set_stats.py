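"""Statistical toolkit: Welch-style two-tailed z-tests, two-sided
Mann-Whitney U, Fisher's exact overlap with Jaccard index, box-plot summaries
and Benjamini-Hochberg adjustment.

Conventions fixed here: the z-test is a Welch two-sample test on means; the
Mann-Whitney test is exact (full enumeration) for combined n <= 16 with no
ties, otherwise normal approximation with tie-corrected variance and
continuity correction; the two-sided Fisher p is the minimum-likelihood sum;
quartiles use linear interpolation between order statistics (numpy's default,
type-7 style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "EnrichmentResult",
    "BoxplotSummary",
    "two_tailed_ztest",
    "mann_whitney_u",
    "fisher_overlap",
    "boxplot_summary",
    "benjamini_hochberg",
    "jaccard_index",
]

EXACT_MW_MAX_N = 16  # combined sample size up to which the exact path is used


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    tail: str = "two-sided"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def two_tailed_ztest(sample_x: Sequence[float], sample_y: Sequence[float]) -> TestResult:
    """Welch two-sample z-test on means with a two-tailed normal p-value.

    Zero pooled variance is degenerate: equal means give z = 0, p = 1;
    unequal means give p = 0 with the degenerate flag set.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("z-test requires at least 3 values per sample")
    se2 = x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y)
    diff = x.mean() - y.mean()
    if se2 == 0:
        if diff == 0:
            return TestResult("ztest", 0.0, 1.0, len(x), len(y), degenerate=True)
        return TestResult(
            "ztest", np.inf if diff > 0 else -np.inf, 0.0, len(x), len(y), degenerate=True
        )
    z = diff / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult("ztest", float(z), float(min(p, 1.0)), len(x), len(y))


def _mw_u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x via midranks."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    rx = ranks[: len(x)].sum()
    return rx - len(x) * (len(x) + 1) / 2.0


def mann_whitney_u(sample_x: Sequence[float], sample_y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the combined sample size is <= 16 and there are no
    ties; otherwise normal approximation with tie-corrected variance and a
    continuity correction.  Two completely identical samples give p = 1.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return TestResult(
            "mannwhitneyu", len(x) * len(y) / 2.0, 1.0, len(x), len(y), degenerate=True
        )
    has_ties = len(np.unique(combined)) < len(combined)
    u = _mw_u_statistic(x, y)
    method = "exact" if (len(combined) <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mannwhitneyu", float(u), float(min(res.pvalue, 1.0)), len(x), len(y))


# ---------------------------------------------------------------------------
# Overlap enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    a: int  # |A ∩ B|
    b: int  # |A \ B|
    c: int  # |B \ A|
    d: int  # |universe \ (A ∪ B)|
    odds_ratio: float
    p_value: float
    jaccard: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")
        if not (0.0 <= self.jaccard <= 1.0):
            raise ValueError("jaccard outside [0, 1]")


def jaccard_index(set_a: Collection, set_b: Collection) -> float:
    sa, sb = set(set_a), set(set_b)
    union = sa | sb
    if not union:
        return 1.0  # two empty sets are identical
    return len(sa & sb) / len(union)


def fisher_overlap(
    set_a: Collection, set_b: Collection, universe: Collection
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of the overlap of two gene sets within a
    declared universe, plus the Jaccard index.

    p is the minimum-likelihood two-sided sum over tables with fixed margins;
    the odds ratio is (a*d)/(b*c) with infinity when b*c = 0 and a*d > 0.
    """
    sa, sb, uni = set(set_a), set(set_b), set(universe)
    for name, s in (("set_a", sa), ("set_b", sb)):
        extra = s - uni
        if extra:
            raise ValueError(
                f"{name} element {sorted(extra)[0]!r} not in universe"
            )
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(uni) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan if a * d == 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=float(odds),
        p_value=float(min(p, 1.0)),
        jaccard=jaccard_index(sa, sb),
    )


# ---------------------------------------------------------------------------
# Box-plot summaries & p adjustment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxplotSummary:
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n_outliers: int


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Five-number summary with 1.5*IQR whiskers and an outlier count.

    Quartiles use linear interpolation between order statistics; whiskers sit
    at the most extreme data points within 1.5*IQR of the quartiles.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotSummary(
        n=len(v),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n_outliers=int(((v < lo_fence) | (v > hi_fence)).sum()),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)
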