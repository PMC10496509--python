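import numpy as np
import pandas as pd
import pytest

from crcscreen.cohorts import CohortDataset
from crcscreen.dependency import DependencyMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20230806)


@pytest.fixture
def tiny_dependency():
    """6 genes x 8 lines, complete data, handmade statuses."""
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(6)] + ["MYC"]
    lines = [f"L{i}" for i in range(8)]
    scores = pd.DataFrame(rng.normal(0, 1, (7, 8)), index=genes,
                          columns=lines)
    status = pd.Series(["wt", "mut"] * 4, index=lines)
    return DependencyMatrix(scores, status)


def make_cohort(cohort_id="C", n_tumors=40, n_pairs=10, seed=0,
                genes=("GA", "GB", "MYC"), mut_frac=0.5):
    """Small structureless cohort used as a base for clinical tests."""
    rng = np.random.default_rng(seed)
    tumors = [f"T{i}" for i in range(n_tumors)]
    normals = [f"N{i}" for i in range(n_pairs)]
    expr = pd.DataFrame(rng.normal(8, 1, (len(genes), n_tumors + n_pairs)),
                        index=list(genes), columns=tumors + normals)
    n_mut = int(round(mut_frac * n_tumors))
    status = np.array(["mut"] * n_mut + ["wt"] * (n_tumors - n_mut))
    rng.shuffle(status)
    ann = pd.DataFrame(index=pd.Index(tumors + normals, name="sample_id"))
    ann["tissue"] = ["tumor"] * n_tumors + ["normal"] * n_pairs
    pair_ids = [f"P{i}" for i in range(n_pairs)]
    ann["pair_id"] = pair_ids + [""] * (n_tumors - n_pairs) + pair_ids
    ann["p53_status"] = list(status) + ["unknown"] * n_pairs
    ann["stage"] = list(rng.integers(1, 5, n_tumors)) + [0] * n_pairs
    ann["time"] = list(rng.uniform(1, 100, n_tumors)) + [np.nan] * n_pairs
    ann["event"] = list(rng.integers(0, 2, n_tumors)) + [0] * n_pairs
    ann["subtype_cms"] = list(rng.choice(
        ["CMS1", "CMS2", "CMS3", "CMS4"], n_tumors)) + ["none"] * n_pairs
    ann["subtype_cris"] = ["none"] * (n_tumors + n_pairs)
    return CohortDataset(cohort_id, expr, ann)


@pytest.fixture
def base_cohort():
    return make_cohort()
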