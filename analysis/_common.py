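"""Shared setup for the analysis drivers: one seeded synthetic study
bundle (2000 genes, 40 cell lines, 2x20 perturbation studies, 15 cohorts
of 100 tumors with 6 p53-annotated) with a single gene planted in every
exemplar role, cached in memory across scripts run in one interpreter."""

from functools import lru_cache
from pathlib import Path

from crcscreen.simulate import gen_screen_bundle

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


@lru_cache(maxsize=1)
def bundle():
    return gen_screen_bundle(n_genes=2000, n_lines=40, n_studies=20,
                             n_cohorts=15, n_p53_cohorts=6, n_tumors=100,
                             seed=SEED)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
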