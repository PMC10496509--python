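"""Readers and writers for the screen's on-disk dialects.

Everything is plain text: TSV for matrices and annotation tables, FASTA for
sequences, JSON for summaries and ground truth.  Writers use fixed float
formatting so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohorts import CohortDataset
from .dependency import DependencyMatrix
from .perturbation import PerturbationStudy

__all__ = [
    "write_dependency", "load_dependency",
    "write_perturbation_panel", "load_perturbation_panel",
    "write_cohorts", "load_cohorts",
    "write_fasta", "load_fasta",
    "write_json", "load_json",
]

FLOAT_FMT = "%.8g"


def _to_tsv(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT,
              index_label=index_label)


# -- dependency -------------------------------------------------------------

def write_dependency(dep: DependencyMatrix, outdir) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _to_tsv(dep.scores, outdir / "dependency.tsv", index_label="gene")
    ann = pd.DataFrame({"p53_status": dep.line_status})
    if dep.lineage is not None:
        ann["lineage"] = dep.lineage
    _to_tsv(ann, outdir / "lines.tsv", index_label="line_id")
    return {"scores": str(outdir / "dependency.tsv"),
            "lines": str(outdir / "lines.tsv")}


def load_dependency(scores_path, lines_path) -> DependencyMatrix:
    scores = pd.read_csv(scores_path, sep="\t", index_col="gene")
    ann = pd.read_csv(lines_path, sep="\t", index_col="line_id")
    if "p53_status" not in ann.columns:
        raise ValueError(f"{lines_path}: missing p53_status column")
    lineage = ann["lineage"] if "lineage" in ann.columns else None
    return DependencyMatrix(scores, ann["p53_status"], lineage)


# -- perturbation panels ----------------------------------------------------

def write_perturbation_panel(panel: list[PerturbationStudy],
                             outdir) -> str:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for study in panel:
        fname = f"study_{study.study_id}.tsv"
        study.table.to_csv(outdir / fname, sep="\t", index=False,
                           float_format=FLOAT_FMT)
        rows.append({"study_id": study.study_id,
                     "regulator": study.regulator,
                     "direction": study.direction,
                     "path": fname})
    manifest = outdir / "panel.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return str(manifest)


def load_perturbation_panel(manifest_path) -> list[PerturbationStudy]:
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path, sep="\t")
    required = {"study_id", "regulator", "direction", "path"}
    if not required <= set(man.columns):
        raise ValueError(f"{manifest_path}: manifest needs {sorted(required)}")
    panel = []
    for _, row in man.iterrows():
        table = pd.read_csv(manifest_path.parent / row["path"], sep="\t")
        panel.append(PerturbationStudy(str(row["study_id"]),
                                       str(row["regulator"]),
                                       str(row["direction"]), table))
    return panel


# -- cohorts ----------------------------------------------------------------

def write_cohorts(cohorts: list[CohortDataset], outdir) -> str:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cohort in cohorts:
        e = f"expression_{cohort.cohort_id}.tsv"
        a = f"annotations_{cohort.cohort_id}.tsv"
        _to_tsv(cohort.expression, outdir / e, index_label="gene")
        _to_tsv(cohort.annotations, outdir / a, index_label="sample_id")
        rows.append({"cohort_id": cohort.cohort_id,
                     "expression": e, "annotations": a})
    manifest = outdir / "cohorts.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return str(manifest)


def load_cohorts(manifest_path, log2: bool = False) -> list[CohortDataset]:
    """Load cohorts listed in a manifest TSV.

    With ``log2=True`` the expression values are transformed as
    ``log2(x + 1)`` (for matrices stored on the linear scale, e.g. RSEM
    normalized counts).
    """
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path, sep="\t")
    cohorts = []
    for _, row in man.iterrows():
        expr = pd.read_csv(manifest_path.parent / row["expression"],
                           sep="\t", index_col="gene")
        ann = pd.read_csv(manifest_path.parent / row["annotations"],
                          sep="\t", index_col="sample_id",
                          keep_default_na=False,
                          na_values=["nan", "NaN", ""])
        for col in ("pair_id", "p53_status", "subtype_cms", "subtype_cris"):
            if col in ann.columns:
                ann[col] = ann[col].fillna("").astype(str)
        if "p53_status" in ann.columns:
            ann.loc[ann["p53_status"] == "", "p53_status"] = "unknown"
        for col in ("subtype_cms", "subtype_cris"):
            if col in ann.columns:
                ann.loc[ann[col] == "", col] = "none"
        if log2:
            expr = np.log2(expr + 1.0)
        cohorts.append(CohortDataset(str(row["cohort_id"]), expr, ann))
    return cohorts


# -- sequences --------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(sequences.items())]
    SeqIO.write(records, str(path), "fasta")


def load_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- json -------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def load_json(path):
    with open(path) as fh:
        return json.load(fh)
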