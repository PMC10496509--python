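"""Vectorized row-wise versions of the elementary tests.

These exist purely for throughput when a screen applies the same test to
thousands of genes; they must agree with the scalar functions in
:mod:`crcscreen.stats` to numerical precision (asserted in the test suite).
Rows with missing values fall back to the scalar path so that the
missing-data policy is identical.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _dist

from .stats import ZeroVarianceError, pearson_test, t_test_unpaired


def pearson_rows(matrix: np.ndarray, vector: np.ndarray, min_pairs: int = 3):
    """Pearson r and two-tailed p of every row of ``matrix`` against
    ``vector`` (pairwise-complete per row).

    Returns ``(r, p, n)`` arrays; rows with fewer than ``min_pairs``
    complete pairs or zero variance get NaN.
    """
    matrix = np.asarray(matrix, dtype=float)
    vector = np.asarray(vector, dtype=float).ravel()
    n_rows = matrix.shape[0]
    r = np.full(n_rows, np.nan)
    p = np.full(n_rows, np.nan)
    n_used = np.zeros(n_rows, dtype=int)

    vec_ok = np.isfinite(vector)
    complete = np.isfinite(matrix).all(axis=1) & vec_ok.all()
    if complete.any():
        sub = matrix[complete]
        xc = sub - sub.mean(axis=1, keepdims=True)
        yc = vector - vector.mean()
        sxx = (xc**2).sum(axis=1)
        syy = float(yc @ yc)
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = (xc @ yc) / np.sqrt(sxx * syy)
        rr = np.clip(rr, -1.0, 1.0)
        n = vector.size
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = rr * np.sqrt((n - 2) / (1.0 - rr**2))
        pp = 2.0 * _dist.t.sf(np.abs(tt), n - 2)
        pp[np.isinf(tt)] = 0.0
        bad = (sxx == 0.0) | (syy == 0.0)
        rr[bad] = np.nan
        pp[bad] = np.nan
        r[complete] = rr
        p[complete] = np.minimum(pp, 1.0)
        n_used[complete] = n
    for i in np.nonzero(~complete)[0]:
        row = matrix[i]
        keep = np.isfinite(row) & vec_ok
        if keep.sum() < min_pairs:
            continue
        try:
            res = pearson_test(row[keep], vector[keep])
        except ZeroVarianceError:
            continue
        r[i], p[i], n_used[i] = res.estimate, res.p_value, res.n
    return r, p, n_used


def ttest_rows(matrix: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray,
               pooled: bool = True):
    """Row-wise two-sample t test of columns ``mask_a`` vs ``mask_b``.

    Returns ``(diff, p)`` with diff = mean(a) - mean(b) per row; rows with
    missing values use the scalar listwise path, degenerate rows get NaN.
    """
    matrix = np.asarray(matrix, dtype=float)
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    n_rows = matrix.shape[0]
    diff = np.full(n_rows, np.nan)
    p = np.full(n_rows, np.nan)
    complete = np.isfinite(matrix).all(axis=1)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if complete.any() and na >= 2 and nb >= 2:
        A = matrix[np.ix_(complete, mask_a)]
        B = matrix[np.ix_(complete, mask_b)]
        va = A.var(axis=1, ddof=1)
        vb = B.var(axis=1, ddof=1)
        d = A.mean(axis=1) - B.mean(axis=1)
        if pooled:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = np.full(d.shape, float(na + nb - 2))
        else:
            se = np.sqrt(va / na + vb / nb)
            with np.errstate(divide="ignore", invalid="ignore"):
                df = (va / na + vb / nb) ** 2 / (
                    (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = d / se
            pp = 2.0 * _dist.t.sf(np.abs(tt), df)
        degenerate = (va == 0.0) & (vb == 0.0)
        d[degenerate] = np.nan
        pp[degenerate] = np.nan
        diff[complete] = d
        p[complete] = np.minimum(pp, 1.0)
    for i in np.nonzero(~complete)[0]:
        row = matrix[i]
        a = row[mask_a]
        b = row[mask_b]
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            continue
        try:
            res = t_test_unpaired(a, b, pooled=pooled)
        except ZeroVarianceError:
            continue
        diff[i], p[i] = res.estimate, res.p_value
    return diff, p
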