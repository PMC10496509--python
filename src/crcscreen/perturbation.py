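"""Vote-counting meta-analysis of regulator-perturbation expression studies.

Each study reports per-gene log2 fold changes and p-values for a gain
(ectopic expression / activation) or loss (knockdown / knockout) of a
regulator (c-MYC or p53).  A gene votes +1 in a study when it behaves as a
target *induced* by the regulator (up after gain, down after loss), -1 when
it behaves as repressed, and 0 otherwise; summing votes across studies
yields the regulator's "GEO expression score", an integer consistency
measure bounded by the number of studies in which the gene was measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .stats import TestResult, pearson_test

__all__ = ["PerturbationStudy", "Vote", "vote", "study_votes", "geo_score",
           "integrate_geo"]

REGULATORS = {"MYC", "p53"}
DIRECTIONS = {"gain", "loss"}


class Vote(NamedTuple):
    """A single study's vote for one gene.  ``measured=False`` (vote 0)
    is distinct from a measured-but-nonsignificant 0."""

    value: int
    measured: bool


@dataclass
class PerturbationStudy:
    """One perturbation experiment's per-gene summary table.

    ``table`` has columns ``gene``, ``log2fc``, ``p`` (gene unique).  For
    the p53 panel only activation-type (gain) studies are admitted.
    """

    study_id: str
    regulator: str
    direction: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.regulator not in REGULATORS:
            raise ValueError(f"unknown regulator {self.regulator!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.regulator == "p53" and self.direction != "gain":
            raise ValueError("p53 panel admits only activation (gain) studies")
        missing = {"gene", "log2fc", "p"} - set(self.table.columns)
        if missing:
            raise ValueError(f"study {self.study_id}: missing {sorted(missing)}")
        if self.table["gene"].duplicated().any():
            raise ValueError(f"study {self.study_id}: duplicated genes")
        fc = self.table["log2fc"]
        if not np.isfinite(fc.to_numpy(dtype=float)).all():
            raise ValueError(f"study {self.study_id}: non-finite log2fc")
        p = self.table["p"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError(f"study {self.study_id}: p outside [0,1]")


def vote(study: PerturbationStudy, gene: str, alpha: float = 0.05,
         fc_min: float = 0.0) -> Vote:
    """Vote of one study for one gene.

    The effective sign is ``sign(log2fc)`` for a gain study and
    ``-sign(log2fc)`` for a loss study (repression after knockdown counts
    as induced-by-regulator); the vote is that sign when ``p < alpha`` and
    ``|log2fc| >= fc_min``, else 0.
    """
    rows = study.table.loc[study.table["gene"] == gene]
    if rows.empty:
        return Vote(0, False)
    log2fc = float(rows["log2fc"].iloc[0])
    p = float(rows["p"].iloc[0])
    sign = int(np.sign(log2fc))
    if study.direction == "loss":
        sign = -sign
    if p < alpha and abs(log2fc) >= fc_min:
        return Vote(sign, True)
    return Vote(0, True)


def study_votes(study: PerturbationStudy, alpha: float = 0.05,
                fc_min: float = 0.0) -> pd.Series:
    """Vectorized votes of one study over all its measured genes."""
    fc = study.table["log2fc"].to_numpy(dtype=float)
    p = study.table["p"].to_numpy(dtype=float)
    sign = np.sign(fc).astype(int)
    if study.direction == "loss":
        sign = -sign
    v = np.where((p < alpha) & (np.abs(fc) >= fc_min), sign, 0)
    return pd.Series(v, index=pd.Index(study.table["gene"], name="gene"),
                     name=study.study_id)


def geo_score(panel: list[PerturbationStudy], regulator: str,
              alpha: float = 0.05, fc_min: float = 0.0) -> pd.DataFrame:
    """Sum study votes into a per-gene score for one regulator panel.

    ``n_studies`` counts only studies in which the gene was measured, so
    ``|score| <= n_studies`` always holds.  Study order is irrelevant.
    """
    if not panel:
        raise ValueError("empty study panel")
    regs = {s.regulator for s in panel}
    if regs != {regulator}:
        raise ValueError(f"panel regulators {sorted(regs)} != {regulator!r}")
    votes = pd.concat([study_votes(s, alpha, fc_min) for s in panel], axis=1)
    score = votes.sum(axis=1, skipna=True).astype(int)
    n_studies = votes.notna().sum(axis=1).astype(int)
    out = pd.DataFrame({"score": score, "n_studies": n_studies})
    out.attrs["alpha"] = alpha
    out.attrs["fc_min"] = fc_min
    out.attrs["regulator"] = regulator
    return out


def integrate_geo(myc_scores: pd.DataFrame,
                  p53_scores: pd.DataFrame) -> TestResult:
    """Pearson correlation between the two regulators' score vectors over
    the shared gene universe (the meta-analysis scatter summary)."""
    genes = myc_scores.index.intersection(p53_scores.index)
    if genes.size < 3:
        raise ValueError("need >= 3 shared genes to integrate the panels")
    return pearson_test(myc_scores.loc[genes, "score"],
                        p53_scores.loc[genes, "score"])
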