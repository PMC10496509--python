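#!/usr/bin/env python
"""Patient-cohort vote scores: driver-correlation votes over 15 cohorts
and p53 wt/mut differential-expression votes over the 6 p53-annotated
cohorts, plus their integration.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import bundle, outdir

from crcscreen import io
from crcscreen.cohorts import cohort_scores


def main() -> None:
    b = bundle()
    scores, integration = cohort_scores(b["cohorts"], "MYC")
    out = outdir("04_cohorts")

    top = scores.reindex(scores["corr_score"]
                         .sub(scores["p53_score"]).sort_values(
                             ascending=False).index).head(50)
    top.to_csv(out / "top_scores.tsv", sep="\t", index_label="gene")
    g = b["planted_gene"]
    io.write_json({
        "integration_r": integration.estimate,
        "integration_p": integration.p_value,
        "planted_gene": g,
        "planted_corr_score": int(scores.loc[g, "corr_score"]),
        "planted_p53_score": int(scores.loc[g, "p53_score"]),
        "n_cohorts_corr": int(scores.loc[g, "n_cohorts_corr"]),
        "n_cohorts_p53": int(scores.loc[g, "n_cohorts_p53"]),
    }, out / "summary.json")

    print(f"cohort score integration: r = {integration.estimate:.3f} "
          f"(p = {integration.p_value:.2g})")
    print(f"planted gene {g}: correlation score "
          f"{int(scores.loc[g, 'corr_score'])}/"
          f"{int(scores.loc[g, 'n_cohorts_corr'])} cohorts, p53 score "
          f"{int(scores.loc[g, 'p53_score'])}/"
          f"{int(scores.loc[g, 'n_cohorts_p53'])} cohorts")


if __name__ == "__main__":
    main()
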