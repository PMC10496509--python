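"""End-to-end screen orchestration: run the available stages, join their
per-gene outputs, flag candidates, and rank genes by a composite of the
per-axis ranks.

The screen's exemplar hit profile is: positive co-dependency with the
driver, stronger dependency in p53-mutant lines, consistently induced by
the driver and repressed by p53 across perturbation studies, positively
correlated with the driver and elevated in p53-mutant tumors across
cohorts.  The composite rank orders genes by the mean of their per-axis
ranks (each axis oriented so that profile comes first); ties break on the
gene identifier.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .cohorts import CohortDataset, cohort_scores
from .dependency import (DependencyMatrix, codependency,
                         differential_dependency, integrate_screen)
from .perturbation import PerturbationStudy, geo_score, integrate_geo
from .stats import TestResult, bh_adjust

__all__ = ["ScreenConfig", "ScreenInputs", "ScreenResult", "run_screen"]


@dataclass
class ScreenConfig:
    """Thresholds and flags of one screen run (echoed into every output)."""

    driver: str = "MYC"
    alpha_dep: float = 0.05
    alpha_geo: float = 0.05
    alpha_cohort: float = 0.05
    fc_min: float = 0.0
    minprop: float = 0.1
    welch: bool = False
    bh: bool = False
    pooled_survival: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_dep", "alpha_geo", "alpha_cohort"):
            a = getattr(self, name)
            if not (0.0 <= a < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {a}")
        if not (0.0 < self.minprop < 0.5):
            raise ValueError("minprop must lie in (0, 0.5)")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ScreenInputs:
    """In-memory inputs; the dependency matrix is required, other stages
    run only when present."""

    dependency: DependencyMatrix
    myc_panel: list[PerturbationStudy] | None = None
    p53_panel: list[PerturbationStudy] | None = None
    cohorts: list[CohortDataset] | None = None


@dataclass
class ScreenResult:
    table: pd.DataFrame
    integrations: dict[str, TestResult | None]
    overlaps: dict[str, int]
    config: ScreenConfig
    stages: list[str]

    def summary(self) -> dict:
        def _tr(t):
            if t is None:
                return None
            return {"r": t.estimate, "p": t.p_value, "n": t.n}
        return {
            "stages": self.stages,
            "n_genes": int(len(self.table)),
            "n_candidates": int(self.table["candidate"].sum()),
            "integrations": {k: _tr(v) for k, v in self.integrations.items()},
            "overlaps": self.overlaps,
            "config": asdict(self.config),
            "config_hash": self.config.hash(),
        }


# axis name -> (column, ascending?) ; ascending axes are those where the
# exemplar profile has the most negative value (p53 repression scores)
_AXES = {
    "codep_r": ("codep_r", False),
    "dep_diff": ("dep_diff", False),
    "myc_geo_score": ("myc_geo_score", False),
    "p53_geo_score": ("p53_geo_score", True),
    "myc_corr_score": ("myc_corr_score", False),
    "p53_cohort_score": ("p53_cohort_score", True),
}


def _composite_rank(table: pd.DataFrame) -> pd.Series:
    ranks = []
    for col, ascending in _AXES.values():
        if col in table.columns and table[col].notna().any():
            ranks.append(table[col].rank(ascending=ascending,
                                         method="average", na_option="keep"))
    if not ranks:
        return pd.Series(np.nan, index=table.index)
    mean_rank = pd.concat(ranks, axis=1).mean(axis=1, skipna=True)
    order = pd.DataFrame({"mean_rank": mean_rank.to_numpy(),
                          "gene_id": list(table.index)}) \
        .sort_values(["mean_rank", "gene_id"])
    composite = np.full(len(order), np.nan)
    composite[:order["mean_rank"].notna().sum()] = \
        np.arange(1, order["mean_rank"].notna().sum() + 1)
    out = pd.Series(composite, index=order["gene_id"].to_numpy())
    return out.reindex(table.index)


def run_screen(inputs: ScreenInputs, config: ScreenConfig | None = None
               ) -> ScreenResult:
    """Execute every available stage and join per-gene outputs on gene id.

    Stage independence: a stage's numbers depend only on its own inputs,
    so omitting one stage never changes another's columns.
    """
    config = config or ScreenConfig()
    stages = ["dependency"]
    codep = codependency(inputs.dependency, config.driver)
    diff = differential_dependency(inputs.dependency,
                                   pooled=not config.welch)
    if config.bh:
        for tab, col in ((codep, "codep_p"), (diff, "dep_diff_p")):
            ok = tab[col].notna()
            tab.loc[ok, col] = bh_adjust(tab.loc[ok, col].to_numpy())
    table, global_r = integrate_screen(codep, diff, alpha=config.alpha_dep)
    integrations: dict[str, TestResult | None] = {"dependency": global_r}
    overlaps = {"dependency": int(len(table))}

    if inputs.myc_panel:
        stages.append("myc_geo")
        myc = geo_score(inputs.myc_panel, "MYC", config.alpha_geo,
                        config.fc_min)
        table = table.join(myc["score"].rename("myc_geo_score"))
        overlaps["myc_geo"] = int(table["myc_geo_score"].notna().sum())
    if inputs.p53_panel:
        stages.append("p53_geo")
        p53 = geo_score(inputs.p53_panel, "p53", config.alpha_geo,
                        config.fc_min)
        table = table.join(p53["score"].rename("p53_geo_score"))
        overlaps["p53_geo"] = int(table["p53_geo_score"].notna().sum())
    if inputs.myc_panel and inputs.p53_panel:
        integrations["geo"] = integrate_geo(myc, p53)
    if inputs.cohorts:
        stages.append("cohorts")
        scores, cohort_integration = cohort_scores(
            inputs.cohorts, config.driver, config.alpha_cohort)
        table = table.join(scores[["corr_score", "p53_score"]].rename(
            columns={"corr_score": "myc_corr_score",
                     "p53_score": "p53_cohort_score"}))
        overlaps["cohorts"] = int(table["myc_corr_score"].notna().sum())
        integrations["cohorts"] = cohort_integration

    table = table.sort_index()
    table["composite_rank"] = _composite_rank(table)
    return ScreenResult(table, integrations, overlaps, config, stages)
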