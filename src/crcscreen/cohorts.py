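"""Patient-cohort vote scores: per-cohort correlation of each gene with a
driver gene (c-MYC) in primary tumors, and per-cohort differential
expression between p53 wt and mutant tumors, summed across cohorts.

Correlation votes use tumor samples only; samples with unknown p53 status
are excluded from the p53 votes but still contribute to correlation votes.
Expression matrices are expected on a log scale (the loader can apply
log2(x+1) on request).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rowstats import pearson_rows, ttest_rows
from .stats import TestResult, ZeroVarianceError, pearson_test, t_test_unpaired

__all__ = ["CohortDataset", "cohort_corr_vote", "p53_diff_vote",
           "cohort_votes", "cohort_scores"]

TISSUES = {"tumor", "normal"}
P53_STATUSES = {"wt", "mut", "unknown"}

ANNOT_DEFAULTS = {
    "pair_id": "", "p53_status": "unknown", "stage": 0,
    "time": np.nan, "event": 0, "subtype_cms": "none", "subtype_cris": "none",
}


@dataclass
class CohortDataset:
    """One patient cohort: gene x sample expression plus clinical annotation.

    ``annotations`` is indexed by sample and carries at least ``tissue``
    ('tumor'/'normal'); optional columns: ``pair_id``, ``p53_status``
    ('wt'/'mut'/'unknown'), ``stage`` (1-4, 0 = unknown), ``time``/``event``
    (relapse-free survival), ``subtype_cms``, ``subtype_cris``.
    """

    cohort_id: str
    expression: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        samples = list(self.expression.columns)
        if list(self.annotations.index) != samples:
            self.annotations = self.annotations.reindex(samples)
            if self.annotations["tissue"].isna().any():
                raise ValueError(
                    f"cohort {self.cohort_id}: annotation/sample mismatch")
        bad = set(self.annotations["tissue"]) - TISSUES
        if bad:
            raise ValueError(f"cohort {self.cohort_id}: bad tissue {bad}")
        for col, default in ANNOT_DEFAULTS.items():
            if col not in self.annotations.columns:
                self.annotations[col] = default
        stages = self.annotations["stage"].fillna(0).astype(int)
        if not stages.isin([0, 1, 2, 3, 4]).all():
            raise ValueError(f"cohort {self.cohort_id}: stage outside 1-4")
        self.annotations["stage"] = stages

    @property
    def tumor_samples(self) -> pd.Index:
        return self.annotations.index[self.annotations["tissue"] == "tumor"]

    def tumor_expression(self) -> pd.DataFrame:
        return self.expression[self.tumor_samples]


def _vote_from_test(p: float, sign: float, alpha: float) -> int:
    if np.isfinite(p) and p < alpha and sign != 0:
        return int(np.sign(sign))
    return 0


def cohort_corr_vote(cohort: CohortDataset, gene: str, driver: str,
                     alpha: float = 0.05) -> int:
    """+1/-1 when the gene correlates significantly (positively /
    negatively) with the driver across the cohort's tumors, else 0."""
    if driver not in cohort.expression.index:
        raise ValueError(f"driver {driver!r} not in cohort {cohort.cohort_id}")
    if gene not in cohort.expression.index:
        return 0
    expr = cohort.tumor_expression()
    try:
        res = pearson_test(expr.loc[gene], expr.loc[driver])
    except (ValueError, ZeroVarianceError):
        return 0
    return _vote_from_test(res.p_value, res.estimate, alpha)


def p53_diff_vote(cohort: CohortDataset, gene: str,
                  alpha: float = 0.05) -> int:
    """+1 when the gene is significantly higher in p53 wt tumors, -1 when
    higher in p53 mutant tumors, else 0 (unknown status excluded)."""
    if gene not in cohort.expression.index:
        return 0
    ann = cohort.annotations
    tumors = ann.index[ann["tissue"] == "tumor"]
    status = ann.loc[tumors, "p53_status"]
    wt = tumors[status == "wt"]
    mut = tumors[status == "mut"]
    x = cohort.expression.loc[gene]
    a = x[wt].dropna()
    b = x[mut].dropna()
    if a.size < 2 or b.size < 2:
        return 0
    try:
        res = t_test_unpaired(a, b)
    except ZeroVarianceError:
        return 0
    return _vote_from_test(res.p_value, res.estimate, alpha)


def cohort_votes(cohort: CohortDataset, driver: str,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Vectorized per-gene votes for one cohort: ``corr_vote`` and
    ``p53_vote`` columns plus measurability flags (NaN votes mean the gene
    was not evaluable in this cohort)."""
    expr = cohort.tumor_expression()
    genes = expr.index
    out = pd.DataFrame(index=genes)
    if driver not in genes:
        raise ValueError(f"driver {driver!r} not in cohort {cohort.cohort_id}")
    r, p, n = pearson_rows(expr.to_numpy(dtype=float),
                           expr.loc[driver].to_numpy(dtype=float))
    corr = np.where(np.isfinite(p) & (p < alpha), np.sign(r), 0.0)
    corr[~np.isfinite(r)] = np.nan
    out["corr_vote"] = corr

    status = cohort.annotations.loc[expr.columns, "p53_status"].to_numpy()
    wt = status == "wt"
    mut = status == "mut"
    if wt.sum() >= 2 and mut.sum() >= 2:
        diff, pt = ttest_rows(expr.to_numpy(dtype=float), wt, mut)
        pv = np.where(np.isfinite(pt) & (pt < alpha), np.sign(diff), 0.0)
        pv[~np.isfinite(diff)] = np.nan
        out["p53_vote"] = pv
    else:
        out["p53_vote"] = np.nan
    return out


def cohort_scores(cohorts: list[CohortDataset], driver: str,
                  alpha: float = 0.05):
    """Sum per-cohort votes into integer scores per gene, and correlate the
    two score vectors (the cohort meta-analysis integration).

    Returns ``(scores, integration)`` where ``scores`` has columns
    ``corr_score``, ``p53_score``, ``n_cohorts_corr``, ``n_cohorts_p53``.
    Cohorts where a gene is unmeasured (or a vote not evaluable) count
    toward neither the score nor its denominator.
    """
    if not cohorts:
        raise ValueError("empty cohort list")
    tabs = [cohort_votes(c, driver, alpha) for c in cohorts]
    corr = pd.concat([t["corr_vote"].rename(c.cohort_id)
                      for t, c in zip(tabs, cohorts)], axis=1)
    p53 = pd.concat([t["p53_vote"].rename(c.cohort_id)
                     for t, c in zip(tabs, cohorts)], axis=1)
    scores = pd.DataFrame({
        "corr_score": corr.sum(axis=1, skipna=True).astype(int),
        "p53_score": p53.sum(axis=1, skipna=True).astype(int),
        "n_cohorts_corr": corr.notna().sum(axis=1).astype(int),
        "n_cohorts_p53": p53.notna().sum(axis=1).astype(int),
    })
    ok = scores.index[scores.index != driver]
    integration: TestResult | None = None
    sub = scores.loc[ok]
    sub = sub[(sub["n_cohorts_corr"] > 0) & (sub["n_cohorts_p53"] > 0)]
    if len(sub) >= 3:
        try:
            integration = pearson_test(sub["corr_score"], sub["p53_score"])
        except ZeroVarianceError:
            integration = None
    return scores, integration
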