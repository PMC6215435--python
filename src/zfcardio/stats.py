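"""Two-sample comparison statistics and screening-efficiency summaries.

The decision rule mirrors a Prism-style workflow: normality of each group is
checked with the D'Agostino–Pearson omnibus K² test; when both groups look
normal (or are too small to test) the comparison is a pooled-variance
two-tailed unpaired Student's t-test, otherwise a two-tailed Mann–Whitney U
test (exact for small untied samples, normal approximation with continuity
and tie correction otherwise). Either test can be forced.

All statistics here are computed from their defining formulas; SciPy is used
only for special functions (regularised incomplete beta for the t tail —
the χ²(2) and normal tails are elementary). Group summaries follow the
mean ± s.d. convention with the n−1 denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache

import numpy as np
from scipy.special import betainc

from .errors import SampleTooSmallError

__all__ = [
    "GroupComparison",
    "EfficiencySummary",
    "dagostino_pearson",
    "compare_groups",
    "screening_efficiency",
    "mann_whitney_u",
    "student_t",
]


@dataclass
class GroupComparison:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float                      # n−1 denominator
    sd_b: float
    normality_p_a: float | None      # None when n < 8
    normality_p_b: float | None
    test_used: str                   # 't' | 'mannwhitney'
    statistic: float
    p_two_tailed: float
    flag: str | None = None          # degenerate-input notes


@dataclass
class EfficiencySummary:
    positives: int
    total: int
    percent: float                   # one decimal, half-up


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

def dagostino_pearson(sample) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus normality test, (K², p).

    K² = Z₁(√b₁)² + Z₂(b₂)², combining the normalising transforms of sample
    skewness (D'Agostino 1970) and kurtosis (Anscombe & Glynn 1983); p comes
    from the χ²(2) upper tail, which is exp(−K²/2). Requires n ≥ 8 — the
    kurtosis transform is undefined for smaller samples.
    """
    x = np.asarray(sample, dtype=np.float64)
    n = x.size
    if n < 8:
        raise SampleTooSmallError(f"D'Agostino–Pearson needs n >= 8, got {n}")
    mu = x.mean()
    d = x - mu
    m2 = np.mean(d**2)
    if m2 == 0:
        raise SampleTooSmallError("zero-variance sample: normality test undefined")
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    g1 = m3 / m2**1.5
    g2 = m4 / m2**2

    # skewness transform
    y = g1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / ((n - 2.0) * (n + 5) * (n + 7) * (n + 9))
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    z1 = delta * math.asinh(y / alpha)

    # kurtosis transform
    eb2 = 3.0 * (n - 1) / (n + 1)
    vb2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (g2 - eb2) / math.sqrt(vb2)
    sqrtb1 = 6.0 * (n**2 - 5 * n + 2) / ((n + 7.0) * (n + 9)) * math.sqrt(
        6.0 * (n + 3) * (n + 5) / (n * (n - 2.0) * (n - 3))
    )
    a = 6.0 + 8.0 / sqrtb1 * (2.0 / sqrtb1 + math.sqrt(1.0 + 4.0 / sqrtb1**2))
    term = (1.0 - 2.0 / a) / (1.0 + xk * math.sqrt(2.0 / (a - 4.0)))
    z2 = ((1.0 - 2.0 / (9.0 * a)) - math.copysign(abs(term) ** (1.0 / 3.0), term)) * math.sqrt(
        9.0 * a / 2.0
    )

    k2 = z1 * z1 + z2 * z2
    p = math.exp(-k2 / 2.0)  # χ²(2) survival function
    return float(k2), float(p)


# ---------------------------------------------------------------------------
# Student's t (pooled variance)
# ---------------------------------------------------------------------------

def student_t(a, b) -> tuple[float, float]:
    """Two-tailed unpaired Student's t-test with pooled variance, (t, p)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise SampleTooSmallError("t-test needs n >= 2 per group")
    m1, m2 = a.mean(), b.mean()
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if sp2 == 0:
        if m1 == m2:
            return 0.0, 1.0
        return math.copysign(math.inf, m1 - m2), 0.0
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    # two-tailed tail mass of Student's t: I_{df/(df+t²)}(df/2, 1/2)
    p = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    return float(t), min(max(p, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

def _rankdata(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties averaged (midranks)."""
    sorter = np.argsort(x, kind="mergesort")
    xs = x[sorter]
    obs = np.r_[True, xs[1:] != xs[:-1]]
    grp = np.cumsum(obs) - 1
    # average rank within each tie group
    counts = np.bincount(grp)
    ends = np.cumsum(counts)
    starts = ends - counts
    avg = (starts + ends + 1) / 2.0  # ranks are 1-based
    out = np.empty(x.size, dtype=np.float64)
    out[sorter] = avg[grp]
    return out


@lru_cache(maxsize=64)
def _ranksum_cdf(n1: int, n2: int) -> np.ndarray:
    """Exact null CDF of U for group sizes (n1, n2), indexed by U = 0..n1·n2.

    Counts subsets of {1..n1+n2} of size n1 by rank sum (dynamic programme
    over elements), then shifts to U = W − n1(n1+1)/2.
    """
    N = n1 + n2
    smax = n1 * N  # loose upper bound on the rank sum
    dp = np.zeros((n1 + 1, smax + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for v in range(1, N + 1):
        for k in range(min(n1, v), 0, -1):
            dp[k, v:] += dp[k - 1, : smax + 1 - v]
    wmin = n1 * (n1 + 1) // 2
    pmf = dp[n1, wmin : wmin + n1 * n2 + 1]
    pmf = pmf / pmf.sum()
    return np.cumsum(pmf)


def mann_whitney_u(a, b) -> tuple[float, float, str]:
    """Two-tailed Mann–Whitney U test, (U, p, method).

    U is the statistic of the first sample. The exact null distribution is
    enumerated when n₁·n₂ ≤ 400 and the data carry no ties; otherwise the
    normal approximation with continuity correction and the tie-corrected
    variance is used. U + U′ = n₁·n₂ always.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise SampleTooSmallError("Mann–Whitney needs n >= 1 per group")
    both = np.concatenate([a, b])
    ranks = _rankdata(both)
    w1 = ranks[:n1].sum()
    u1 = w1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(both).size < both.size
    if not has_ties and n1 * n2 <= 400:
        cdf = _ranksum_cdf(n1, n2)
        u = int(round(u1))
        lo = cdf[u]                           # P(U <= u)
        hi = 1.0 - (cdf[u - 1] if u > 0 else 0.0)  # P(U >= u)
        p = min(2.0 * min(lo, hi), 1.0)
        return float(u1), float(p), "exact"
    # normal approximation with tie correction
    N = n1 + n2
    _, counts = np.unique(both, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (N * (N - 1.0))
    var = n1 * n2 / 12.0 * ((N + 1.0) - tie_term)
    if var == 0:
        return float(u1), 1.0, "normal"
    mu = n1 * n2 / 2.0
    z = (u1 - mu - math.copysign(0.5, u1 - mu)) / math.sqrt(var) if u1 != mu else 0.0
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return float(u1), min(p, 1.0), "normal"


# ---------------------------------------------------------------------------
# the comparison layer
# ---------------------------------------------------------------------------

def compare_groups(a, b, policy: str = "auto") -> GroupComparison:
    """Compare two samples with the normality-gated two-test policy.

    ``policy='auto'``: Student's t when both groups pass D'Agostino–Pearson
    at α = 0.05 (groups with n < 8 count as passing — too small to test),
    else Mann–Whitney. ``'t'`` or ``'mwu'`` force the respective test.
    Degenerate inputs (zero variance in both groups) are flagged: p = 1 for
    equal means, p = 0 otherwise.
    """
    if policy not in ("auto", "t", "mwu"):
        raise ValueError(f"policy must be 'auto', 't' or 'mwu', got {policy!r}")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise SampleTooSmallError("need n >= 2 per group")

    def _norm_p(x: np.ndarray) -> float | None:
        if x.size < 8 or np.ptp(x) == 0:
            return None
        return dagostino_pearson(x)[1]

    pa, pb = _norm_p(a), _norm_p(b)
    flag = None
    if policy == "auto":
        normal_a = pa is None or pa > 0.05
        normal_b = pb is None or pb > 0.05
        use_t = normal_a and normal_b
    else:
        use_t = policy == "t"

    degenerate = a.var(ddof=1) == 0 and b.var(ddof=1) == 0
    if degenerate:
        stat, p = (0.0, 1.0) if a.mean() == b.mean() else (math.copysign(math.inf, a.mean() - b.mean()), 0.0)
        flag = "zero variance in both groups"
        test = "t" if use_t else "mannwhitney"
    elif use_t:
        stat, p = student_t(a, b)
        test = "t"
    else:
        stat, p, _method = mann_whitney_u(a, b)
        test = "mannwhitney"
    return GroupComparison(
        n_a=a.size, n_b=b.size,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        normality_p_a=pa, normality_p_b=pb,
        test_used=test, statistic=float(stat), p_two_tailed=float(p),
        flag=flag,
    )


def screening_efficiency(positives: int, total: int) -> EfficiencySummary:
    """Proportion of positive clutches/larvae as a percentage to one decimal.

    Rounding is half-up (so 20/28 → 71.4%, 21/28 → 75.0%), matching how
    screening efficiencies are conventionally reported.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= positives <= total:
        raise ValueError(f"positives must lie in [0, total], got {positives}/{total}")
    pct = Decimal(100 * positives) / Decimal(total)
    pct = pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return EfficiencySummary(positives=positives, total=total, percent=float(pct))
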