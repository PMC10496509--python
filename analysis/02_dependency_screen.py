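#!/usr/bin/env python
"""Dependency screen: per-gene co-dependency with the driver and
p53-mutant differential dependency, and their integration.

Finds that the two dependency axes correlate positively across the genome
(the planted driver-status coupling), and that the planted gene sits among
the candidates (significant on both axes with the required signs).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import bundle, outdir

from crcscreen import io
from crcscreen.dependency import (codependency, differential_dependency,
                                  integrate_screen)


def main() -> None:
    b = bundle()
    codep = codependency(b["dependency"], "MYC")
    diff = differential_dependency(b["dependency"])
    table, global_r = integrate_screen(codep, diff)
    out = outdir("02_dependency")

    candidates = table[table["candidate"]].sort_values("codep_p")
    candidates.to_csv(out / "candidates.tsv", sep="\t", index_label="gene",
                      float_format="%.4g")
    io.write_json({
        "global_r": global_r.estimate, "global_p": global_r.p_value,
        "n_genes": int(len(table)),
        "n_candidates": int(table["candidate"].sum()),
        "planted_gene": b["planted_gene"],
        "planted_is_candidate": bool(
            table.loc[b["planted_gene"], "candidate"]),
    }, out / "summary.json")

    g = b["planted_gene"]
    print(f"axes integration: r = {global_r.estimate:.3f} "
          f"(p = {global_r.p_value:.2g}) over {global_r.n} genes")
    print(f"{int(table['candidate'].sum())} candidate genes")
    print(f"planted gene {g}: codep_r = {table.loc[g, 'codep_r']:.3f}, "
          f"dep_diff = {table.loc[g, 'dep_diff']:.3f}, "
          f"candidate = {bool(table.loc[g, 'candidate'])}")


if __name__ == "__main__":
    main()
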