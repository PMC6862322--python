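"""Two-sample inference for small histology/physiology datasets.

The module provides the decision tree used throughout the pipeline:
a Kolmogorov-Smirnov (Lilliefors) normality gate, Student/Welch t tests
(from raw data or printed summary statistics), an exact Wilcoxon rank-sum
test by full enumeration of rank assignments, the Hodges-Lehmann shift
estimate with its exact Mann-Whitney confidence interval, and
one-way ANOVA / Friedman blocks with Bonferroni-corrected pairwise
comparisons.

Conventions
-----------
* All tests are two-sided.
* ``estimate`` in a :class:`ComparisonResult` is always the location of the
  *second* sample minus the location of the first (``b - a``).
* The exact rank-sum path enumerates all ``C(n_a + n_b, n_a)`` assignments
  of pooled (mid)ranks, so it is valid under ties; it is used whenever
  ``n_a + n_b <= 20``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from retinaquant._exceptions import InsufficientDataError, ValidationError

__all__ = [
    "SampleSummary",
    "ComparisonResult",
    "summarize",
    "ks_normality",
    "two_sample_t",
    "t_from_summary",
    "wilcoxon_exact",
    "hodges_lehmann",
    "anova_bonferroni",
    "friedman",
    "compare",
]

_EPS = 1e-9


@dataclass(frozen=True)
class SampleSummary:
    """Location/scale summary of one sample (mean +/- SD, median +/- IQR)."""

    n: int
    mean: float
    sd: float
    median: float
    iqr: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.sd < 0 or self.iqr < 0:
            raise ValidationError("sd and iqr must be >= 0")


@dataclass
class ComparisonResult:
    """Outcome of one two-group (or omnibus) comparison.

    ``estimate`` is the mean difference (t paths) or the Hodges-Lehmann
    median difference (rank-sum path), always second-minus-first group.
    """

    method: str
    p_value: float
    estimate: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    ci_level: float = math.nan
    statistic: float = math.nan
    df: float = math.nan
    correction: str = "none"
    family_m: int = 1
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0 + _EPS):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")
        self.p_value = min(float(self.p_value), 1.0)
        if math.isfinite(self.estimate) and math.isfinite(self.ci_low):
            if not (self.ci_low - _EPS <= self.estimate <= self.ci_high + _EPS):
                raise ValidationError("estimate outside its confidence interval")


def summarize(sample) -> SampleSummary:
    x = _as_sample(sample, "sample")
    q75, q25 = np.percentile(x, [75, 25])
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return SampleSummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        median=float(np.median(x)),
        iqr=float(q75 - q25),
    )


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------


def _lilliefors_stat(x: np.ndarray) -> float:
    """KS distance of a standardized sample to the standard normal CDF."""
    n = x.shape[-1]
    z = (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, ddof=1, keepdims=True)
    z = np.sort(z, axis=-1)
    cdf = stats.norm.cdf(z)
    grid = np.arange(1, n + 1) / n
    d_plus = np.max(grid - cdf, axis=-1)
    d_minus = np.max(cdf - (grid - 1.0 / n), axis=-1)
    return np.maximum(d_plus, d_minus)


def ks_normality(sample, n_sims: int = 2000, seed: int = 0) -> float:
    """Lilliefors-corrected one-sample KS p-value against a fitted normal.

    The null distribution of the KS statistic (with mean and SD estimated
    from the data) is obtained by seeded Monte-Carlo simulation; the
    returned p uses the ``(1 + k) / (1 + n_sims)`` estimator so it is never
    exactly zero.
    """
    x = _as_sample(sample, "sample")
    if x.size < 4:
        raise InsufficientDataError("normality test requires n >= 4")
    if np.ptp(x) == 0:
        raise ValidationError("sample is constant; normality is undefined")
    d_obs = float(_lilliefors_stat(x[None, :])[0])
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((int(n_sims), x.size))
    d_sim = _lilliefors_stat(sims)
    return float((1 + np.sum(d_sim >= d_obs - _EPS)) / (1 + n_sims))


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------


def t_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    pooled: bool = True,
    ci_level: float = 0.95,
) -> ComparisonResult:
    """Two-sided two-sample t test computed from printed moments.

    Lets published ``mean +/- SD`` tables be tested directly.  ``estimate``
    is ``mean_b - mean_a``.
    """
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValidationError("standard deviations must be >= 0")
    if sd_a == 0 and sd_b == 0:
        raise ValidationError("zero variance in both groups")
    va, vb = sd_a**2, sd_b**2
    if pooled:
        df = n_a + n_b - 2
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        method = "student_t"
    else:
        se = math.sqrt(va / n_a + vb / n_b)
        df = (va / n_a + vb / n_b) ** 2 / (
            (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
        )
        method = "welch_t"
    diff = mean_b - mean_a
    t = diff / se if se > 0 else 0.0
    p = 1.0 if se == 0 else 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df)
    return ComparisonResult(
        method=method,
        p_value=min(max(p, np.finfo(float).tiny), 1.0),
        estimate=diff,
        ci_low=diff - tcrit * se,
        ci_high=diff + tcrit * se,
        ci_level=ci_level,
        statistic=t,
        df=float(df),
    )


def two_sample_t(a, b, pooled: bool = True, ci_level: float = 0.95) -> ComparisonResult:
    """Two-sided Student (pooled) or Welch t test on raw data."""
    xa = _as_sample(a, "a")
    xb = _as_sample(b, "b")
    if xa.size < 2 or xb.size < 2:
        raise ValidationError("each group needs n >= 2")
    return t_from_summary(
        float(np.mean(xa)),
        float(np.std(xa, ddof=1)),
        xa.size,
        float(np.mean(xb)),
        float(np.std(xb, ddof=1)),
        xb.size,
        pooled=pooled,
        ci_level=ci_level,
    )


# ---------------------------------------------------------------------------
# Exact Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _exact_ranksum_p(ranks: np.ndarray, n_a: int) -> float:
    """Two-sided p by full enumeration of rank assignments.

    ``ranks`` are the pooled midranks; the observed statistic is the sum of
    the first ``n_a`` of them.  Valid under ties because the enumeration is
    over the observed (mid)rank multiset.
    """
    w_obs = float(np.sum(ranks[:n_a]))
    sums = np.fromiter(
        (sum(c) for c in combinations(ranks.tolist(), n_a)),
        dtype=float,
        count=math.comb(ranks.size, n_a),
    )
    p_le = np.mean(sums <= w_obs + _EPS)
    p_ge = np.mean(sums >= w_obs - _EPS)
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_exact(a, b, exact_limit: int = 20) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test, exact for ``n_a + n_b <= exact_limit``.

    The exact path computes ``p = 2 * min(P(W <= w), P(W >= w))`` (capped at
    1) over all ``C(n_a + n_b, n_a)`` assignments of the pooled midranks.
    Larger samples fall back to the tie-corrected normal approximation.
    """
    xa = _as_sample(a, "a")
    xb = _as_sample(b, "b")
    pooled = np.concatenate([xa, xb])
    ranks = stats.rankdata(pooled)
    if xa.size + xb.size <= exact_limit:
        p = _exact_ranksum_p(ranks, xa.size)
        method = "wilcoxon_exact"
        w = float(np.sum(ranks[: xa.size]))
    else:
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
        p, w, method = float(res.pvalue), float(res.statistic), "wilcoxon_normal_approx"
    return ComparisonResult(method=method, p_value=max(p, np.finfo(float).tiny), statistic=w)


def _mannwhitney_u_pmf(m: int, n: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic (no ties), length m*n + 1.

    Built from the generating function of partitions into at most ``m``
    parts each at most ``n`` (Gaussian binomial coefficient).
    """
    # recurrence N_{m,n}(u) = N_{m-1,n}(u - n) + N_{m,n-1}(u)
    table = np.zeros((m + 1, n + 1, m * n + 1))
    table[0, :, 0] = 1.0
    table[:, 0, 0] = 1.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            shifted = np.zeros(m * n + 1)
            shifted[j:] = table[i - 1, j, : m * n + 1 - j]
            table[i, j] = shifted + table[i, j - 1]
    pmf = table[m, n]
    return pmf / pmf.sum()


def hodges_lehmann(a, b, ci_level: float = 0.95) -> ComparisonResult:
    """Hodges-Lehmann shift estimate ``b - a`` with its exact rank-sum CI.

    The estimate is the median of all ``n_a * n_b`` pairwise differences;
    the confidence bounds are order statistics of those differences at ranks
    taken from the exact null Mann-Whitney distribution, so the interval
    inverts the exact test (conservative for small n).
    """
    xa = _as_sample(a, "a")
    xb = _as_sample(b, "b")
    diffs = np.sort((xb[:, None] - xa[None, :]).ravel())
    est = float(np.median(diffs))
    m, n = xa.size, xb.size
    alpha = 1.0 - ci_level
    if m * n <= 400:
        pmf = _mannwhitney_u_pmf(m, n)
        cdf = np.cumsum(pmf)
        # largest k with P(U <= k - 1) <= alpha/2 ; k >= 1
        k = int(np.searchsorted(cdf, alpha / 2.0 + _EPS, side="right"))
        k = max(k, 1)
        achieved = 1.0 - 2.0 * float(cdf[k - 1])
    else:  # normal approximation of the U distribution for the CI ranks
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        k = int(np.floor(m * n / 2.0 - z * np.sqrt(m * n * (m + n + 1) / 12.0)))
        k = max(k, 1)
        achieved = ci_level
    lo = float(diffs[k - 1])
    hi = float(diffs[m * n - k])
    p = _exact_ranksum_p(stats.rankdata(np.concatenate([xa, xb])), m) if m + n <= 20 else float(
        stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic").pvalue
    )
    return ComparisonResult(
        method="hodges_lehmann",
        p_value=max(p, np.finfo(float).tiny),
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        ci_level=float(achieved),
    )


# ---------------------------------------------------------------------------
# Omnibus designs
# ---------------------------------------------------------------------------


def anova_bonferroni(
    groups, family_m: int | None = None, ci_level: float = 0.95
) -> tuple[ComparisonResult, list[tuple[int, int, ComparisonResult]]]:
    """One-way ANOVA plus pairwise pooled-t comparisons with Bonferroni.

    Returns the omnibus F result and a list of ``(i, j, result)`` for every
    group pair, where each pairwise p has been multiplied by ``family_m``
    (default: the number of pairs) and capped at 1.
    """
    samples = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(samples) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    for i, s in enumerate(samples):
        if s.size < 2:
            raise ValidationError(f"group {i} needs n >= 2")
    if all(np.ptp(s) == 0 for s in samples) and len({float(s[0]) for s in samples}) == 1:
        raise ValidationError("all groups constant and identical; F undefined")
    f_stat, f_p = stats.f_oneway(*samples)
    overall = ComparisonResult(
        method="anova",
        p_value=float(min(max(f_p, np.finfo(float).tiny), 1.0)),
        statistic=float(f_stat),
    )
    pairs = list(combinations(range(len(samples)), 2))
    m = int(family_m) if family_m is not None else len(pairs)
    out = []
    for i, j in pairs:
        res = two_sample_t(samples[i], samples[j], pooled=True, ci_level=ci_level)
        res.p_value = min(1.0, res.p_value * m)
        res.correction = "bonferroni"
        res.family_m = m
        out.append((i, j, res))
    return overall, out


def friedman(
    data, family_m: int | None = None
) -> tuple[ComparisonResult, list[tuple[int, int, ComparisonResult]]]:
    """Friedman chi-square over a complete block design (blocks x treatments).

    Pairwise follow-up uses the Wilcoxon signed-rank test with Bonferroni
    correction over the treatment pairs.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValidationError("blocked data must be 2-D (blocks x treatments)")
    if not np.all(np.isfinite(x)):
        raise ValidationError("incomplete blocks: data contains NaN/inf")
    n_blocks, k = x.shape
    if k < 2 or n_blocks < 2:
        raise ValidationError("need >= 2 treatments and >= 2 blocks")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n_blocks * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n_blocks * (k + 1)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
    overall = ComparisonResult(
        method="friedman", p_value=max(p, np.finfo(float).tiny), statistic=float(chi2), df=k - 1
    )
    pairs = list(combinations(range(k), 2))
    m = int(family_m) if family_m is not None else len(pairs)
    out = []
    for i, j in pairs:
        d = x[:, j] - x[:, i]
        if np.all(d == 0):
            res = ComparisonResult(method="signed_rank", p_value=1.0)
        else:
            sr = stats.wilcoxon(x[:, i], x[:, j])
            res = ComparisonResult(
                method="signed_rank",
                p_value=float(min(max(sr.pvalue, np.finfo(float).tiny), 1.0)),
                statistic=float(sr.statistic),
            )
        res.p_value = min(1.0, res.p_value * m)
        res.correction = "bonferroni"
        res.family_m = m
        out.append((i, j, res))
    return overall, out


# ---------------------------------------------------------------------------
# Decision tree
# ---------------------------------------------------------------------------


def compare(
    a,
    b,
    method: str = "auto",
    alpha: float = 0.05,
    pooled: bool = True,
    ci_level: float = 0.95,
    seed: int = 0,
) -> ComparisonResult:
    """Two-group comparison following the normality/sample-size gate.

    ``auto`` applies the parametric path (pooled t) only when both groups
    have n >= 30 *and* both pass the KS normality gate at ``alpha``;
    otherwise the exact rank-sum test with a Hodges-Lehmann estimate is
    used.  The chosen path is recorded in ``ComparisonResult.method``.
    """
    xa = _as_sample(a, "a")
    xb = _as_sample(b, "b")
    if method == "auto":
        parametric = xa.size >= 30 and xb.size >= 30
        if parametric:
            parametric = (
                ks_normality(xa, seed=seed) > alpha and ks_normality(xb, seed=seed + 1) > alpha
            )
        method = "t" if parametric else "wilcoxon"
    if method == "t":
        return two_sample_t(xa, xb, pooled=pooled, ci_level=ci_level)
    if method == "wilcoxon":
        hl = hodges_lehmann(xa, xb, ci_level=ci_level)
        w = wilcoxon_exact(xa, xb)
        hl.method = w.method
        hl.p_value = w.p_value
        hl.statistic = w.statistic
        return hl
    raise ValidationError(f"unknown method {method!r}")


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr
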