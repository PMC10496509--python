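#!/usr/bin/env python
"""Clinical associations of the planted gene: tumor-vs-normal paired fold
changes per cohort (forest table), stage trend, and molecular-subtype
comparison.
"""

import dataclasses
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import bundle, outdir

import pandas as pd

from crcscreen import io
from crcscreen.clinical import (paired_tumor_normal, stage_trend,
                                subtype_compare)


def main() -> None:
    b = bundle()
    g = b["planted_gene"]
    out = outdir("05_clinical")

    forest = [dataclasses.asdict(paired_tumor_normal(c, g))
              for c in b["cohorts"]]
    forest_df = pd.DataFrame(forest)
    forest_df.to_csv(out / "forest.tsv", sep="\t", index=False,
                     float_format="%.4g")
    n_up = int(((forest_df["fold_change"] > 1) & (forest_df["p"] < 0.05))
               .sum())

    trends = {}
    for c in b["cohorts"]:
        t = stage_trend(c, g)
        trends[c.cohort_id] = {"contrast": t.estimate, "p": t.p_value}
    n_trend = sum(1 for v in trends.values()
                  if v["p"] < 0.05 and v["contrast"] > 0)

    sub = subtype_compare(b["cohorts"][0], g, "CMS")
    io.write_json({
        "gene": g,
        "tumor_elevated_cohorts": n_up, "n_cohorts": len(forest),
        "stage_trend_positive_cohorts": n_trend,
        "stage_trends": trends,
        "cms_argmax": sub["argmax"],
        "cms_anova_p": sub["anova"].p_value,
        "cms_means": sub["means"],
    }, out / "summary.json")

    print(f"gene {g}: tumor-elevated (fc > 1, p < 0.05) in "
          f"{n_up}/{len(forest)} cohorts")
    print(f"positive stage trend in {n_trend}/{len(trends)} cohorts")
    print(f"highest-expressing CMS subtype: {sub['argmax']} "
          f"(ANOVA p = {sub['anova'].p_value:.2g})")


if __name__ == "__main__":
    main()
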