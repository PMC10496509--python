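#!/usr/bin/env python
"""Vote-count meta-analysis of the perturbation panels.

Sums +1/-1 significance-and-direction votes per gene over 20 driver
gain/loss studies and 20 p53-activation studies; the two score vectors
correlate inversely, and the planted gene scores near the +20/-20 bounds.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import bundle, outdir

import pandas as pd

from crcscreen import io
from crcscreen.perturbation import geo_score, integrate_geo, study_votes


def main() -> None:
    b = bundle()
    myc = geo_score(b["myc_panel"], "MYC")
    p53 = geo_score(b["p53_panel"], "p53")
    res = integrate_geo(myc, p53)
    out = outdir("03_perturbation")

    g = b["planted_gene"]
    per_study = pd.DataFrame({
        s.study_id: {"direction": s.direction,
                     "log2fc": float(s.table.set_index("gene")
                                     .loc[g, "log2fc"]),
                     "vote": int(study_votes(s).loc[g])}
        for s in b["myc_panel"] + b["p53_panel"]}).T
    per_study.to_csv(out / "planted_gene_votes.tsv", sep="\t",
                     index_label="study", float_format="%.3f")
    io.write_json({
        "integration_r": res.estimate, "integration_p": res.p_value,
        "planted_gene": g,
        "planted_myc_score": int(myc.loc[g, "score"]),
        "planted_p53_score": int(p53.loc[g, "score"]),
        "n_studies_per_panel": int(myc.loc[g, "n_studies"]),
    }, out / "summary.json")

    print(f"driver vs p53 score integration: r = {res.estimate:.3f} "
          f"(p = {res.p_value:.2g}) over {res.n} genes")
    print(f"planted gene {g}: driver score "
          f"{int(myc.loc[g, 'score'])}/{int(myc.loc[g, 'n_studies'])}, "
          f"p53 score {int(p53.loc[g, 'score'])}/"
          f"{int(p53.loc[g, 'n_studies'])}")


if __name__ == "__main__":
    main()
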