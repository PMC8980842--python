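"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV (first column feature ids, header row sample ids),
sequences as FASTA, annotations as TSV with a ``sample_id`` column, and
ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix, ExpressionMatrix, SampleAnnotation
from .simulate import GroundTruth, SyntheticDataset

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "read_ground_truth",
    "write_ground_truth",
    "write_dataset",
    "ParseError",
]

_ALPHABETS = {"DNA": set("ACGTN"), "RNA": set("ACGUN")}


class ParseError(ValueError):
    pass


def read_matrix_tsv(path, kind: str = "gene") -> ExpressionMatrix | CountMatrix:
    """Read a feature x sample TSV matrix.

    ``kind`` is ``"gene"`` or ``"mir"`` for expression values, or
    ``"counts"`` for an integer count matrix.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    dup = sorted({s for s in samples if samples.count(s) > 1})
    if dup:
        raise ParseError(f"{path}: duplicate sample ids {dup}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index.name = None
    raw.columns.name = None
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature ids {dup}")
    try:
        values = raw.astype(float)
    except ValueError:
        for i, row in enumerate(raw.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} at line {i + 2}, "
                        f"column {raw.columns[j]!r}"
                    ) from None
        raise
    if values.isna().to_numpy().any():
        i, j = np.argwhere(values.isna().to_numpy())[0]
        raise ParseError(f"{path}: missing/ragged cell at line {i + 2}, column {values.columns[j]!r}")
    if kind == "counts":
        arr = values.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ParseError(
                f"{path}: non-integer count {arr[i, j]} at feature {values.index[i]!r}, "
                f"sample {values.columns[j]!r}"
            )
        return CountMatrix(values)
    return ExpressionMatrix(values, kind=kind)


def write_matrix_tsv(matrix, path) -> None:
    df = matrix.data if hasattr(matrix, "data") else matrix
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_fasta(path, alphabet: str = "DNA") -> dict[str, str]:
    """id -> uppercase sequence; validates against the DNA or RNA alphabet."""
    if alphabet not in _ALPHABETS:
        raise ParseError(f"unknown alphabet {alphabet!r}")
    allowed = _ALPHABETS[alphabet]
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty record {record.id!r}")
        bad = set(seq) - allowed
        if bad:
            raise ParseError(
                f"{path}: record {record.id!r} has characters {sorted(bad)} "
                f"outside the {alphabet} alphabet"
            )
        if record.id in out:
            raise ParseError(f"{path}: duplicate record id {record.id!r}")
        out[record.id] = seq
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_annotation(path) -> SampleAnnotation:
    table = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SampleAnnotation(table)


def write_annotation(annotation: SampleAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="sample_id")


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "gene_modules": truth.gene_modules.to_dict(),
        "disease_modules": list(truth.disease_modules),
        "regulators": {m: [mod, c] for m, (mod, c) in truth.regulators.items()},
        "true_targets": truth.true_targets.to_dict(orient="records"),
        "factors": {m: truth.factors.loc[m].to_dict() for m in truth.factors.index},
        "responders": {
            s: (None if pd.isna(v) else v) for s, v in truth.responders.items()
        },
        "mir_sequences": truth.mir_sequences,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    factors = pd.DataFrame(payload["factors"]).T
    return GroundTruth(
        gene_modules=pd.Series(payload["gene_modules"], name="module"),
        disease_modules=payload["disease_modules"],
        regulators={m: (mod, c) for m, (mod, c) in payload["regulators"].items()},
        true_targets=pd.DataFrame(
            payload["true_targets"],
            columns=["mir_id", "gene_id", "site_type", "start", "end"],
        ),
        factors=factors,
        responders=pd.Series(payload["responders"], dtype="object"),
        mir_sequences=payload["mir_sequences"],
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write a synthetic cohort to a directory of plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "gene_expression.tsv",
        "mir_counts": outdir / "mir_counts.tsv",
        "annotation": outdir / "samples.tsv",
        "utrs": outdir / "utrs.fasta",
        "mir_seqs": outdir / "mir_sequences.fasta",
        "truth": outdir / "ground_truth.json",
    }
    write_matrix_tsv(dataset.genes, paths["genes"])
    write_matrix_tsv(dataset.mirs, paths["mir_counts"])
    write_annotation(dataset.annotation, paths["annotation"])
    write_fasta(dataset.utrs, paths["utrs"])
    write_fasta(dataset.truth.mir_sequences, paths["mir_seqs"])
    write_ground_truth(dataset.truth, paths["truth"])
    return paths
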