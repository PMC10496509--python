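#!/usr/bin/env python
"""Generate the synthetic study inputs and write them to scratch/data/.

One gene is planted with every exemplar-hit role (driver co-dependency,
stronger dependency in p53-mutant lines, induction by the driver,
repression by p53, driver correlation and p53-mutant elevation in patient
cohorts, and a p53-dependent survival interaction); the planted truth is
recorded alongside the files so later steps can be audited against it.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import SCRATCH, SEED, bundle

from crcscreen import io
from crcscreen.simulate import gen_sequences


def main() -> None:
    b = bundle()
    d = SCRATCH / "data"
    io.write_dependency(b["dependency"], d / "dependency")
    io.write_perturbation_panel(b["myc_panel"], d / "geo_myc")
    io.write_perturbation_panel(b["p53_panel"], d / "geo_p53")
    io.write_cohorts(b["cohorts"], d / "cohorts")
    b["truth"].to_json(d / "truth.json")

    utrs, orthologs, promoters, seq_truth = gen_sequences(seed=SEED)
    io.write_fasta(utrs, d / "utrs.fasta")
    io.write_fasta(promoters, d / "promoters.fasta")
    for uid, orth in orthologs.items():
        io.write_fasta(orth, d / f"orthologs_{uid}.fasta")
    seq_truth.to_json(d / "sequence_truth.json")

    print(f"bundle written to {d} (seed {SEED})")
    print(f"planted exemplar gene: {b['planted_gene']}")
    print(f"gene universe: {b['truth'].params['n_genes']} genes, "
          f"{b['truth'].params['n_lines']} cell lines, "
          f"{b['truth'].params['n_studies']}x2 perturbation studies, "
          f"{b['truth'].params['n_cohorts']} cohorts")


if __name__ == "__main__":
    main()
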