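"""Univariate statistical battery for demographics and band features.

Two-tailed two-sample t-tests (pooled Student or Welch, from raw samples or
published summary statistics), 2x2 chi-square with optional Yates continuity
correction, one-way ANOVA with Bonferroni-corrected pairwise t-tests, the
star coding used for significance annotation, and the size-weighted pooled
mean used to combine subgroup summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "t_test_two_sample",
    "chi_square_2x2",
    "anova_bonferroni",
    "bonferroni_adjust",
    "significance_stars",
    "weighted_pooled_mean",
]


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and sample standard deviation of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.sd > 0 and self.n < 2:
            raise ValueError("a nonzero sd requires n >= 2")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def _as_summary(group) -> GroupSummary:
    if isinstance(group, GroupSummary):
        return group
    arr = np.asarray(group, dtype=float)
    if arr.size < 2:
        raise ValueError("raw samples need n >= 2")
    return GroupSummary(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


def t_test_two_sample(a, b, variant: str = "student") -> TestResult:
    """Two-tailed two-sample t-test from raw samples or group summaries.

    ``variant="student"`` pools variances (df = n_a + n_b - 2);
    ``variant="welch"`` uses the Satterthwaite approximation.  Zero variance
    in both groups gives p = 1 when the means coincide and a degenerate
    p = 0 limit otherwise.
    """
    sa, sb = _as_summary(a), _as_summary(b)
    if min(sa.n, sb.n) < 2:
        raise ValueError("both groups need n >= 2")
    diff = sa.mean - sb.mean
    if variant == "student":
        df = sa.n + sb.n - 2
        pooled = ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / df
        se = math.sqrt(pooled * (1 / sa.n + 1 / sb.n))
        method = "student t"
    elif variant == "welch":
        va, vb = sa.sd**2 / sa.n, sb.sd**2 / sb.n
        se = math.sqrt(va + vb)
        if se > 0:
            df = (va + vb) ** 2 / (
                va**2 / (sa.n - 1) + vb**2 / (sb.n - 1)
            )
        else:
            df = sa.n + sb.n - 2
        method = "welch t"
    else:
        raise ValueError("variant must be 'student' or 'welch'")
    if se == 0:
        if diff == 0:
            return TestResult(0.0, df, 1.0, method, degenerate=True)
        return TestResult(math.copysign(math.inf, diff), df, 0.0, method,
                          degenerate=True)
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)), method)


def chi_square_2x2(a: int, b: int, c: int, d: int,
                   correction: str = "yates") -> TestResult:
    """Chi-square test of independence on the 2x2 table [[a, b], [c, d]].

    With the Yates continuity correction (default),
    chi2 = N (|ad - bc| - N/2)^2 / [(a+b)(c+d)(a+c)(b+d)], clamped to 0
    when |ad - bc| <= N/2; p from the chi-square distribution with 1 df.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise ValueError("chi-square undefined: a table margin is zero")
    det = abs(a * d - b * c)
    if correction == "yates":
        det = max(det - n / 2.0, 0.0)
        method = "chi-square (Yates)"
    elif correction == "none":
        method = "chi-square"
    else:
        raise ValueError("correction must be 'yates' or 'none'")
    chi2 = n * det**2 / math.prod(margins)
    return TestResult(float(chi2), 1.0, float(sps.chi2.sf(chi2, 1)), method)


def bonferroni_adjust(p: float, m: int) -> float:
    """Single-step Bonferroni: min(p * m, 1)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(p * m, 1.0)


def anova_bonferroni(groups) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA plus all pairwise Student t-tests, Bonferroni-adjusted.

    Returns ``(omnibus, pairwise)``; each pairwise result carries the
    adjusted p-value (raw p times the number of comparisons, clipped to 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    f, p = sps.f_oneway(*groups)
    k = len(groups)
    omnibus = TestResult(float(f), float(k - 1), float(p), "one-way ANOVA")
    m = k * (k - 1) // 2
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            res = t_test_two_sample(groups[i], groups[j], variant="student")
            pairwise.append(
                TestResult(res.statistic, res.df,
                           bonferroni_adjust(res.p_value, m),
                           "student t (Bonferroni)", res.degenerate)
            )
    return omnibus, pairwise


def significance_stars(p: float) -> str:
    """Star coding: **** <1e-4, *** <1e-3, ** <0.01, * <0.05, else 'ns'.

    Thresholds are strict, so p = 0.05 exactly codes as 'ns' even though the
    significance decision rule elsewhere is "0.05 or less".
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    for thresh, code in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thresh:
            return code
    return "ns"


def weighted_pooled_mean(summaries) -> float:
    """Size-weighted mean of group means: sum(n_i mean_i) / sum(n_i)."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("need at least one summary")
    tot = sum(s.n for s in summaries)
    if tot == 0:
        raise ValueError("total n is zero")
    return sum(s.n * s.mean for s in summaries) / tot
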