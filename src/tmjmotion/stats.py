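"""Two-group comparison statistics for the kinematic indices.

Patient (Group A) vs control (Group B) comparisons use a normality-gated
two-sample test: if both groups pass Shapiro–Wilk at alpha, a
pooled-variance t-test with df = nA + nB - 2 and its 95% CI; otherwise a
Mann–Whitney U test with the Hodges–Lehmann shift estimate and a rank-based
CI.  The difference is always mean(B) - mean(A) (control minus patient).

A summaries-only path reconstructs the pooled t-test from (mean, SEM, n)
per group, for comparing against published tables without raw data.  Note
that printed "mean ± x" values here are treated as mean ± SEM: that is the
reading under which published standard errors and CIs are internally
consistent with the group sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import StatsError

__all__ = [
    "GroupSummary",
    "DifferenceEstimate",
    "DirectionCounts",
    "summarize",
    "compare_groups",
    "compare_from_summaries",
    "compare_directions",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, moments and a normality check for one group."""

    n: int
    mean: float
    sd: float                       # n-1 denominator
    sem: float                      # sd / sqrt(n)
    normality_p: float | None       # Shapiro–Wilk; None if n < 3 or sd == 0


@dataclass(frozen=True)
class DifferenceEstimate:
    """Mean/location difference mean(B) - mean(A) with its uncertainty."""

    diff: float
    se: float | None
    ci_low: float
    ci_high: float
    df: float | None
    p: float
    test: str                       # "pooled_t" | "welch_t" | "mann_whitney"


@dataclass(frozen=True)
class DirectionCounts:
    """Per-group counts of leftward / rightward / no deviation calls."""

    left: int
    right: int
    none: int = 0

    def __post_init__(self):
        if min(self.left, self.right, self.none) < 0:
            raise StatsError("direction counts must be nonnegative")


def summarize(values) -> GroupSummary:
    """Mean, SD (ddof=1), SEM and Shapiro–Wilk normality p for one group."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise StatsError("need at least 2 one-dimensional observations")
    if not np.isfinite(x).all():
        raise StatsError("non-finite observations")
    n = len(x)
    sd = float(np.std(x, ddof=1))
    normality_p = None
    if n >= 3 and sd > 0:
        normality_p = float(sps.shapiro(x).pvalue)
    return GroupSummary(n=n, mean=float(np.mean(x)), sd=sd,
                        sem=sd / math.sqrt(n), normality_p=normality_p)


def _pooled_t(mean_a, sd_a, n_a, mean_b, sd_b, n_b, alpha=0.05):
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    se = math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    diff = mean_b - mean_a
    if se == 0:
        raise StatsError("zero pooled variance: no test possible")
    tq = float(sps.t.ppf(1.0 - alpha / 2.0, df))
    t_stat = diff / se
    p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    return DifferenceEstimate(diff=diff, se=se, ci_low=diff - tq * se,
                              ci_high=diff + tq * se, df=df, p=p, test="pooled_t")


def _hodges_lehmann_ci(a, b, alpha=0.05):
    """HL shift estimate (median of b_i - a_j) and rank-based CI.

    CI bounds are order statistics of the pairwise differences at ranks
    from the normal approximation to the Mann–Whitney U distribution.
    """
    diffs = np.sort((b[:, None] - a[None, :]).ravel())
    m, n = len(a), len(b)
    N = m * n
    hl = float(np.median(diffs))
    z = float(sps.norm.ppf(1.0 - alpha / 2.0))
    k = int(math.floor(N / 2.0 - z * math.sqrt(m * n * (m + n + 1) / 12.0)))
    k = max(k, 1)
    return hl, float(diffs[k - 1]), float(diffs[N - k])


def compare_groups(a, b, alpha: float = 0.05, welch: bool = False) -> DifferenceEstimate:
    """Normality-gated two-group comparison, difference = mean(B) - mean(A).

    Both groups normal by Shapiro–Wilk at ``alpha``: pooled-variance t-test
    (or Welch if requested).  Otherwise: two-sided Mann–Whitney U with the
    Hodges–Lehmann location shift and its rank-based 95% CI.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    sa, sb = summarize(xa), summarize(xb)
    if sa.sd == 0 and sb.sd == 0 and sa.mean == sb.mean:
        raise StatsError("both groups constant and identical: no test possible")

    normal = all(s.normality_p is None or s.normality_p >= alpha for s in (sa, sb))
    if normal and not welch:
        return _pooled_t(sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n, alpha)
    if normal and welch:
        res = sps.ttest_ind(xb, xa, equal_var=False)
        se = math.sqrt(sa.sem**2 + sb.sem**2)
        df = float(res.df)
        tq = float(sps.t.ppf(1.0 - alpha / 2.0, df))
        diff = sb.mean - sa.mean
        return DifferenceEstimate(diff=diff, se=se, ci_low=diff - tq * se,
                                  ci_high=diff + tq * se, df=df,
                                  p=float(res.pvalue), test="welch_t")
    u = sps.mannwhitneyu(xb, xa, alternative="two-sided")
    hl, lo, hi = _hodges_lehmann_ci(xa, xb, alpha)
    return DifferenceEstimate(diff=hl, se=None, ci_low=lo, ci_high=hi,
                              df=None, p=float(u.pvalue), test="mann_whitney")


def compare_from_summaries(mean_a: float, sem_a: float, n_a: int,
                           mean_b: float, sem_b: float, n_b: int,
                           alpha: float = 0.05) -> DifferenceEstimate:
    """Pooled-variance t comparison reconstructed from (mean, SEM, n) pairs.

    sd = SEM * sqrt(n) per group; then the pooled two-sample t machinery is
    identical to :func:`compare_groups`'s t path, so feeding it the
    summaries of raw data reproduces that result exactly.
    """
    vals = [mean_a, sem_a, mean_b, sem_b]
    if not all(np.isfinite(v) for v in vals):
        raise StatsError("non-finite summary inputs")
    if sem_a <= 0 or sem_b <= 0 or n_a < 2 or n_b < 2:
        raise StatsError("need positive SEMs and n >= 2 per group")
    sd_a = sem_a * math.sqrt(n_a)
    sd_b = sem_b * math.sqrt(n_b)
    return _pooled_t(mean_a, sd_a, n_a, mean_b, sd_b, n_b, alpha)


def compare_directions(a: DirectionCounts, b: DirectionCounts,
                       allow_chi2: bool = False) -> tuple[float, str]:
    """Compare left/right deviation frequencies between the two groups.

    Builds the 2x2 left/right table (``none`` calls excluded) and runs
    Fisher's exact test; when all expected counts are >= 5 and ``allow_chi2``
    is set, a chi-square test is used instead and labelled as such.
    """
    table = np.array([[a.left, a.right], [b.left, b.right]], dtype=float)
    if table.sum() == 0:
        raise StatsError("all left/right counts are zero: nothing to compare")
    if allow_chi2:
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        if row.min() > 0 and col.min() > 0:
            expected = row * col / table.sum()
            if (expected >= 5).all():
                chi2 = sps.chi2_contingency(table, correction=False)
                return float(chi2.pvalue), "chi_square"
    res = sps.fisher_exact(table.astype(int), alternative="two-sided")
    return float(res.pvalue), "fisher_exact"
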