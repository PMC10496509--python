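"""Elementary statistics used throughout the screen.

Every test here is implemented from its textbook formula so that each stage
of the screen is auditable against closed forms; only distribution functions
(Student t, F, studentized range, normal) come from :mod:`scipy.stats`.

All two-group and correlation tests return a :class:`TestResult`; p-values
are two-tailed.  Missing values (NaN) are removed pairwise for correlation
and listwise within each group elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _dist

__all__ = [
    "TestResult",
    "TukeyPair",
    "ZeroVarianceError",
    "pearson_test",
    "t_test_unpaired",
    "t_test_paired",
    "anova_oneway",
    "linear_trend_test",
    "tukey_hsd",
    "bh_adjust",
]


class ZeroVarianceError(ValueError):
    """Raised when a test is degenerate because every value is identical."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    Attributes
    ----------
    statistic : float
        The test statistic (t, F, r-derived t, or contrast t).
    p_value : float
        Two-tailed p-value in [0, 1].
    df : float or tuple of float
        Degrees of freedom; a ``(df1, df2)`` pair for F tests.
    estimate : float
        The effect estimate: Pearson r, mean difference, or trend contrast.
    ci_low, ci_high : float
        95% confidence bounds where defined, else NaN.
    n : int
        Number of observations actually used (after missing-data removal).
    method : str
        Short name of the procedure.
    """

    statistic: float
    p_value: float
    df: float | tuple[float, float]
    estimate: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    n: int = 0
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0,1]: {self.p_value}")


@dataclass(frozen=True)
class TukeyPair:
    """One pairwise comparison from a Tukey HSD post-test."""

    group1: int
    group2: int
    estimate: float  # mean(group1) - mean(group2)
    statistic: float  # studentized range q
    p_value: float
    df: float
    ci_low: float = math.nan
    ci_high: float = math.nan


def _clean(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    return arr[np.isfinite(arr)]


def pearson_test(x, y) -> TestResult:
    """Pearson correlation with two-tailed p-value and Fisher-z 95% CI.

    Pairs with a missing value in either vector are dropped before anything
    is computed (pairwise-complete).  The p-value uses the exact t transform
    ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0:
        raise ZeroVarianceError("x has zero variance")
    if syy == 0.0:
        raise ZeroVarianceError("y has zero variance")
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if 1.0 - r * r <= 0.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
        lo = hi = r
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * _dist.t.sf(abs(t), n - 2)
        if n > 3:
            z = math.atanh(r)
            half = 1.96 / math.sqrt(n - 3)
            lo, hi = math.tanh(z - half), math.tanh(z + half)
        else:
            lo = hi = math.nan
    return TestResult(t, min(p, 1.0), n - 2, r, lo, hi, n, "pearson")


def t_test_unpaired(a, b, pooled: bool = True) -> TestResult:
    """Two-sample t test, classical Student (``pooled=True``) or Welch.

    estimate is ``mean(a) - mean(b)``.
    """
    a = _clean(a, "a")
    b = _clean(b, "b")
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs n >= 2 (got {na}, {nb})")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    if va == 0.0 and vb == 0.0:
        raise ZeroVarianceError("both groups have zero variance")
    est = float(a.mean() - b.mean())
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
        method = "student-t"
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        method = "welch-t"
    t = est / se
    p = 2.0 * _dist.t.sf(abs(t), df)
    crit = _dist.t.ppf(0.975, df)
    return TestResult(t, min(p, 1.0), df, est, est - crit * se, est + crit * se,
                      na + nb, method)


def t_test_paired(pre, post) -> TestResult:
    """Paired t test: a one-sample t on ``post - pre``.

    estimate is the mean difference (post minus pre) with its 95% CI.
    """
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.size != post.size:
        raise ValueError(f"length mismatch: {pre.size} vs {post.size}")
    keep = np.isfinite(pre) & np.isfinite(post)
    d = (post - pre)[keep]
    n = int(d.size)
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise ZeroVarianceError("differences have zero variance")
    est = float(d.mean())
    se = sd / math.sqrt(n)
    t = est / se
    p = 2.0 * _dist.t.sf(abs(t), n - 1)
    crit = _dist.t.ppf(0.975, n - 1)
    return TestResult(t, min(p, 1.0), n - 1, est, est - crit * se,
                      est + crit * se, n, "paired-t")


def _group_arrays(groups) -> list[np.ndarray]:
    cleaned = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    for i, g in enumerate(cleaned):
        if g.size < 2:
            raise ValueError(f"group {i} needs n >= 2 (got {g.size})")
    return cleaned


def anova_oneway(groups) -> TestResult:
    """One-way fixed-effects ANOVA over >= 2 groups.

    Returns F on ``(k-1, N-k)`` degrees of freedom.  If every value in the
    data is identical, F is defined as 0 with p = 1.
    """
    gs = _group_arrays(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.size for g in gs])
    N = int(ns.sum())
    means = np.array([g.mean() for g in gs])
    grand = float(np.concatenate(gs).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df1, df2 = float(k - 1), float(N - k)
    if ssw == 0.0:
        if ssb == 0.0:
            return TestResult(0.0, 1.0, (df1, df2), 0.0, n=N, method="anova")
        return TestResult(math.inf, 0.0, (df1, df2), ssb / df1, n=N,
                          method="anova")
    F = (ssb / df1) / (ssw / df2)
    p = _dist.f.sf(F, df1, df2)
    return TestResult(F, min(p, 1.0), (df1, df2), ssb / df1, n=N, method="anova")


def linear_trend_test(groups, scores=None) -> TestResult:
    """Post-test for linear trend across ordered groups.

    Contrast coefficients are the centered group scores (default the group
    positions 1..k, e.g. tumor stages 1-4); the contrast
    ``L = sum(c_i * mean_i)`` is tested with
    ``t = L / sqrt(MSE * sum(c_i^2 / n_i))`` on ``N - k`` df, two-tailed.
    """
    gs = _group_arrays(groups)
    k = len(gs)
    if k < 3:
        raise ValueError("trend test needs at least 3 ordered groups")
    if scores is None:
        scores = np.arange(1, k + 1, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if scores.size != k:
        raise ValueError("scores length must equal number of groups")
    c = scores - scores.mean()
    ns = np.array([g.size for g in gs])
    N = int(ns.sum())
    means = np.array([g.mean() for g in gs])
    L = float(c @ means)
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df = float(N - k)
    if ssw == 0.0:
        raise ZeroVarianceError("zero within-group variance; trend t undefined")
    mse = ssw / df
    se = math.sqrt(mse * float((c**2 / ns).sum()))
    t = L / se
    p = 2.0 * _dist.t.sf(abs(t), df)
    crit = _dist.t.ppf(0.975, df)
    return TestResult(t, min(p, 1.0), df, L, L - crit * se, L + crit * se, N,
                      "linear-trend")


def tukey_hsd(groups) -> list[TukeyPair]:
    """Tukey(-Kramer) multiple-comparison post-test for >= 3 groups.

    p-values come from the studentized range distribution with ``k`` groups
    and ``N - k`` error degrees of freedom; unbalanced designs use the
    Tukey-Kramer standard error.
    """
    gs = _group_arrays(groups)
    k = len(gs)
    if k < 3:
        raise ValueError("Tukey post-test needs at least 3 groups")
    ns = np.array([g.size for g in gs])
    N = int(ns.sum())
    means = np.array([g.mean() for g in gs])
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df = float(N - k)
    if ssw == 0.0:
        raise ZeroVarianceError("zero within-group variance")
    mse = ssw / df
    qcrit = float(_dist.studentized_range.ppf(0.95, k, df))
    out: list[TukeyPair] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            se = math.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p = float(_dist.studentized_range.sf(q, k, df))
            out.append(TukeyPair(i, j, diff, q, min(max(p, 0.0), 1.0), df,
                                 diff - qcrit * se, diff + qcrit * se))
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (optional, off by
    default everywhere in the screen)."""
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
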