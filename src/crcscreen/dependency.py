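"""CRISPR-dependency screen: per-gene co-dependency with a driver gene and
p53-status-stratified differential dependency, integrated into a candidate
list.

Dependency scores follow the DepMap orientation: lower (more negative)
score = the cell line depends more on the gene.  Consequently a positive
``dep_diff = mean(wt) - mean(mut)`` means mutant lines have *lower* scores,
i.e. a stronger dependency in p53-mutant lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rowstats import pearson_rows, ttest_rows
from .stats import TestResult, pearson_test

__all__ = [
    "DependencyMatrix",
    "codependency",
    "differential_dependency",
    "integrate_screen",
]

MAX_MISSING_FRAC = 0.5


@dataclass
class DependencyMatrix:
    """Gene x cell-line dependency scores with per-line p53 status.

    ``scores``: DataFrame, genes as rows, cell lines as columns.
    ``line_status``: Series over the same lines with values 'wt'/'mut'.
    ``lineage``: optional Series used to restrict to one tumor type.
    """

    scores: pd.DataFrame
    line_status: pd.Series
    lineage: pd.Series | None = None

    def __post_init__(self) -> None:
        lines = list(self.scores.columns)
        missing = [l for l in lines if l not in self.line_status.index]
        if missing:
            raise ValueError(f"lines without p53 status: {missing[:5]}")
        bad = set(self.line_status.loc[lines]) - {"wt", "mut"}
        if bad:
            raise ValueError(f"invalid p53 status values: {sorted(bad)}")
        self.line_status = self.line_status.loc[lines]
        if self.lineage is not None:
            self.lineage = self.lineage.reindex(lines)

    def restrict_lineage(self, lineage: str) -> "DependencyMatrix":
        if self.lineage is None:
            raise ValueError("no lineage annotation available")
        keep = self.lineage[self.lineage == lineage].index
        return DependencyMatrix(self.scores[keep], self.line_status.loc[keep])

    @property
    def mut_mask(self) -> np.ndarray:
        return (self.line_status == "mut").to_numpy()


def _drop_sparse(dep: DependencyMatrix) -> tuple[pd.DataFrame, list[str]]:
    frac_missing = dep.scores.isna().mean(axis=1)
    dropped = list(dep.scores.index[frac_missing > MAX_MISSING_FRAC])
    return dep.scores.drop(index=dropped), dropped


def codependency(dep: DependencyMatrix, driver: str,
                 min_pairs: int = 3) -> pd.DataFrame:
    """Pearson correlation of every gene's dependency profile with the
    driver's profile across cell lines.

    Returns a DataFrame indexed by gene with ``codep_r``, ``codep_p``,
    ``n`` and ``evaluable``; genes with fewer than ``min_pairs`` complete
    pairs (or constant profiles) are flagged not evaluable.  Genes missing
    in more than half the lines are dropped (listed in ``attrs['dropped']``).
    """
    if driver not in dep.scores.index:
        raise ValueError(f"driver gene {driver!r} not in dependency matrix")
    scores, dropped = _drop_sparse(dep)
    if driver not in scores.index:
        raise ValueError(f"driver gene {driver!r} has too much missing data")
    drv = scores.loc[driver].to_numpy(dtype=float)
    r, p, n = pearson_rows(scores.to_numpy(dtype=float), drv, min_pairs)
    out = pd.DataFrame({"codep_r": r, "codep_p": p, "n": n},
                       index=scores.index)
    out["evaluable"] = np.isfinite(r)
    out["is_driver"] = out.index == driver
    out.attrs["dropped"] = dropped
    out.attrs["driver"] = driver
    return out


def differential_dependency(dep: DependencyMatrix,
                            pooled: bool = True) -> pd.DataFrame:
    """Per-gene wt-vs-mut dependency difference.

    ``dep_diff = mean(wt scores) - mean(mut scores)``; positive values mean
    stronger dependency (lower score) in p53-mutant lines.  p-values come
    from the two-sample t test (Student by default, Welch optional).
    """
    mut = dep.mut_mask
    wt = ~mut
    if wt.sum() < 2 or mut.sum() < 2:
        raise ValueError(
            f"need >= 2 lines per p53 status (wt={wt.sum()}, mut={mut.sum()})")
    scores, dropped = _drop_sparse(dep)
    diff, p = ttest_rows(scores.to_numpy(dtype=float), wt, mut, pooled=pooled)
    out = pd.DataFrame({"dep_diff": diff, "dep_diff_p": p}, index=scores.index)
    out["evaluable"] = np.isfinite(diff)
    out.attrs["dropped"] = dropped
    out.attrs["n_wt"] = int(wt.sum())
    out.attrs["n_mut"] = int(mut.sum())
    return out


def integrate_screen(codep: pd.DataFrame, diff: pd.DataFrame,
                     alpha: float = 0.05):
    """Join the two dependency axes, flag candidates, and compute the
    global correlation between them (the screen's scatter summary).

    A candidate shows a significant *positive* co-dependency with the
    driver and a significant *stronger* dependency in p53-mutant lines:
    ``codep_p < alpha and codep_r > 0 and dep_diff_p < alpha and
    dep_diff > 0``.  The driver itself is excluded from candidacy.
    Returns ``(table, global_r)``.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    genes = codep.index.intersection(diff.index)
    if genes.empty:
        raise ValueError("no shared genes between the two dependency axes")
    tab = codep.loc[genes, ["codep_r", "codep_p", "n", "is_driver"]].join(
        diff.loc[genes, ["dep_diff", "dep_diff_p"]])
    tab["candidate"] = (
        (tab["codep_p"] < alpha) & (tab["codep_r"] > 0)
        & (tab["dep_diff_p"] < alpha) & (tab["dep_diff"] > 0)
        & ~tab["is_driver"]
    )
    ok = tab["codep_r"].notna() & tab["dep_diff"].notna() & ~tab["is_driver"]
    if ok.sum() >= 3:
        global_r: TestResult | None = pearson_test(
            tab.loc[ok, "codep_r"], tab.loc[ok, "dep_diff"])
    else:
        global_r = None
    return tab, global_r
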