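"""Clinical associations of a gene's expression within patient cohorts:
paired tumor-vs-normal fold changes (forest-plot entries), expression trend
across tumor stages, molecular-subtype comparisons, and high-vs-low
expression survival analysis with optional p53 stratification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import CohortDataset
from .stats import (TestResult, ZeroVarianceError, anova_oneway,
                    linear_trend_test, t_test_paired, tukey_hsd)
from .survival import StratumResult, optimal_cutoff, stratified_survival

__all__ = ["ForestEntry", "paired_tumor_normal", "stage_trend",
           "subtype_compare", "survival_by_gene"]


@dataclass(frozen=True)
class ForestEntry:
    """One cohort's tumor-vs-normal fold change for a gene.

    ``fold_change`` is on the linear scale (2 ** mean log2 paired
    difference); the CI is the exponentiated t-based interval of the mean
    log2 difference.  ``note`` flags degenerate cases.
    """

    cohort_id: str
    fold_change: float
    ci_low: float
    ci_high: float
    p: float
    n_pairs: int
    note: str = ""


def _paired_values(cohort: CohortDataset, gene: str):
    """Match tumor/normal sample pairs via pair_id; unpaired samples are
    ignored (their ids are returned for logging)."""
    if gene not in cohort.expression.index:
        raise ValueError(f"gene {gene!r} not in cohort {cohort.cohort_id}")
    ann = cohort.annotations
    paired = ann[ann["pair_id"].astype(str) != ""]
    tumors, normals, unpaired = [], [], []
    for pid, sub in paired.groupby("pair_id"):
        t = sub.index[sub["tissue"] == "tumor"]
        n = sub.index[sub["tissue"] == "normal"]
        if len(t) == 1 and len(n) == 1:
            tumors.append(t[0])
            normals.append(n[0])
        else:
            unpaired.extend(sub.index)
    x = cohort.expression.loc[gene]
    return x[tumors].to_numpy(float), x[normals].to_numpy(float), unpaired


def paired_tumor_normal(cohort: CohortDataset, gene: str) -> ForestEntry:
    """Paired t test of tumor vs matched normal expression (log2 scale),
    reported as a linear-scale fold change with 95% CI."""
    tumor, normal, unpaired = _paired_values(cohort, gene)
    if tumor.size < 2:
        raise ValueError(
            f"cohort {cohort.cohort_id}: need >= 2 complete pairs, "
            f"got {tumor.size}")
    note = f"{len(unpaired)} unpaired samples ignored" if unpaired else ""
    try:
        res = t_test_paired(normal, tumor)  # estimate = tumor - normal
    except ZeroVarianceError:
        fc = float(2.0 ** np.mean(tumor - normal))
        return ForestEntry(cohort.cohort_id, fc, math.nan, math.nan,
                           math.nan, tumor.size,
                           (note + "; " if note else "")
                           + "zero-variance differences (degenerate)")
    return ForestEntry(cohort.cohort_id, 2.0 ** res.estimate,
                       2.0 ** res.ci_low, 2.0 ** res.ci_high, res.p_value,
                       res.n, note)


def stage_trend(cohort: CohortDataset, gene: str,
                min_per_stage: int = 2) -> TestResult:
    """Linear-trend post-test of tumor expression across stages 1-4."""
    if gene not in cohort.expression.index:
        raise ValueError(f"gene {gene!r} not in cohort {cohort.cohort_id}")
    ann = cohort.annotations
    tumors = ann.index[(ann["tissue"] == "tumor") & (ann["stage"] > 0)]
    x = cohort.expression.loc[gene, tumors]
    stages = ann.loc[tumors, "stage"]
    groups, scores = [], []
    for s in (1, 2, 3, 4):
        vals = x[stages == s].dropna().to_numpy(float)
        if vals.size >= min_per_stage:
            groups.append(vals)
            scores.append(float(s))
    if len(groups) < 3:
        raise ValueError(
            f"cohort {cohort.cohort_id}: need >= 3 populated stages, "
            f"got {len(groups)}")
    return linear_trend_test(groups, scores)


def subtype_compare(cohort: CohortDataset, gene: str, scheme: str = "CMS"):
    """ANOVA + Tukey post-test of tumor expression across molecular
    subtypes (CMS or CRIS labels, which are inputs, not computed here).

    Returns a dict with the ANOVA result, group means/ns, the label of the
    highest-mean subtype, the Tukey pairs, and a ``no_signal`` flag when
    the ANOVA finds nothing.
    """
    col = {"CMS": "subtype_cms", "CRIS": "subtype_cris"}.get(scheme)
    if col is None:
        raise ValueError(f"unknown subtype scheme {scheme!r}")
    if gene not in cohort.expression.index:
        raise ValueError(f"gene {gene!r} not in cohort {cohort.cohort_id}")
    ann = cohort.annotations
    tumors = ann.index[(ann["tissue"] == "tumor") & (ann[col] != "none")]
    x = cohort.expression.loc[gene, tumors]
    labels = sorted(ann.loc[tumors, col].unique())
    groups = [x[ann.loc[tumors, col] == lab].dropna().to_numpy(float)
              for lab in labels]
    keep = [i for i, g in enumerate(groups) if g.size >= 2]
    labels = [labels[i] for i in keep]
    groups = [groups[i] for i in keep]
    if len(groups) < 2:
        raise ValueError(f"cohort {cohort.cohort_id}: need >= 2 subtypes")
    anova = anova_oneway(groups)
    means = {lab: float(g.mean()) for lab, g in zip(labels, groups)}
    ns = {lab: int(g.size) for lab, g in zip(labels, groups)}
    argmax = max(means, key=means.get)
    pairs = []
    if len(groups) >= 3:
        pairs = [
            {"group1": labels[t.group1], "group2": labels[t.group2],
             "diff": t.estimate, "p": t.p_value}
            for t in tukey_hsd(groups)
        ]
    return {
        "scheme": scheme,
        "anova": anova,
        "means": means,
        "n": ns,
        "argmax": argmax,
        "tukey": pairs,
        "no_signal": bool(anova.p_value >= 0.05),
    }


def _survival_frame(cohorts: list[CohortDataset], gene: str,
                    pooled: bool) -> pd.DataFrame:
    frames = []
    for cohort in cohorts:
        if gene not in cohort.expression.index:
            continue
        ann = cohort.annotations
        tumors = ann.index[(ann["tissue"] == "tumor")
                           & np.isfinite(ann["time"].astype(float))
                           & (ann["time"].astype(float) > 0)]
        if tumors.empty:
            continue
        expr = cohort.expression.loc[gene, tumors].astype(float)
        if pooled:
            expr = expr - expr.median()  # remove per-cohort platform offset
        frames.append(pd.DataFrame({
            "cohort": cohort.cohort_id,
            "time": ann.loc[tumors, "time"].astype(float),
            "event": ann.loc[tumors, "event"].astype(int),
            "expression": expr,
            "stratum": ann.loc[tumors, "p53_status"],
        }))
    if not frames:
        raise ValueError("no cohort provides survival data for this gene")
    return pd.concat(frames, axis=0)


def survival_by_gene(cohorts, gene: str, stratify_by_p53: bool = False,
                     pooled: bool = True, minprop: float = 0.1):
    """High-vs-low expression survival analysis for one gene.

    ``pooled=True`` concatenates cohorts after per-cohort median-centering
    of the gene's expression and runs a single cutoff scan;
    ``pooled=False`` returns one result per cohort.  With
    ``stratify_by_p53`` the optimal-cutoff analysis runs independently in
    the p53 wt and mut strata (unknown-status patients are dropped).
    Results are :class:`StratumResult`-shaped dicts.
    """
    if isinstance(cohorts, CohortDataset):
        cohorts = [cohorts]
    frame = _survival_frame(cohorts, gene, pooled)

    def _analyze(sub: pd.DataFrame) -> dict[str, StratumResult]:
        if stratify_by_p53:
            known = sub[sub["stratum"].isin(["wt", "mut"])]
            return stratified_survival(known, minprop=minprop)
        try:
            c, comp = optimal_cutoff(sub["time"].to_numpy(),
                                     sub["event"].to_numpy(),
                                     sub["expression"].to_numpy(), minprop)
            return {"all": StratumResult("all", True, c, comp)}
        except ValueError as exc:
            return {"all": StratumResult("all", False, reason=str(exc))}

    if pooled:
        return _analyze(frame)
    return {cid: _analyze(sub) for cid, sub in frame.groupby("cohort")}
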