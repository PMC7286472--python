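"""Readers and writers for the pipeline's exchange formats.

Tabular interchange is TSV throughout; sequences travel as FASTA (60-char
wrap) with a companion transcript attribute TSV, and gene sets as GMT.
Every writer produces files its reader accepts unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reannotate import TranscriptRecord
from .stats import GeneSetCollection

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_stage_tsv",
    "write_stage_tsv",
    "read_probe_tsv",
    "read_attributes_tsv",
    "read_transcripts",
    "write_fasta",
    "read_survival_tsv",
    "read_gmt",
    "write_gmt",
]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-x-samples TSV (first column ids, header = sample ids).

    Ragged rows, duplicate ids and non-numeric cells are rejected with the
    offending line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise ValueError(
                    f"{path.name}:{lineno}: expected {n_cols} fields, got {len(fields)}"
                )
            ids.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-numeric cell ({exc})") from None
    index = pd.Index(ids, name=header[0] or "gene_id")
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValueError(f"{path.name}: duplicate id {dup!r}")
    matrix = pd.DataFrame(rows, index=index, columns=header[1:])
    if not np.isfinite(matrix.to_numpy()).all():
        raise ValueError(f"{path.name}: non-finite values")
    return matrix


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "gene_id")


def read_stage_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "stage"]:
        raise ValueError(f"{Path(path).name}: expected columns sample, stage")
    return pd.Series(df["stage"].to_numpy(), index=df["sample"], name="stage")


def write_stage_tsv(stages: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": stages.index, "stage": stages.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_probe_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["probe_id", "probeset_id", "sequence"]
    if list(df.columns[: len(required)]) != required:
        raise ValueError(f"{Path(path).name}: expected columns {required}")
    return df[required]


def read_attributes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["transcript_id", "gene_id", "gene_symbol", "biotype"]
    if list(df.columns[: len(required)]) != required:
        raise ValueError(f"{Path(path).name}: expected columns {required}")
    return df[required]


def read_transcripts(fasta: str | Path, attrs: pd.DataFrame) -> list[TranscriptRecord]:
    """Join a transcript FASTA with its attribute table into records."""
    meta = attrs.set_index("transcript_id")
    records = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id not in meta.index:
            raise KeyError(f"transcript {rec.id!r} missing from attribute table")
        row = meta.loc[rec.id]
        records.append(
            TranscriptRecord(
                transcript_id=rec.id,
                gene_id=row["gene_id"],
                gene_symbol=row["gene_symbol"],
                biotype=row["biotype"],
                sequence=str(rec.seq).upper(),
            )
        )
    return records


def write_fasta(records: list[TranscriptRecord], path: str | Path) -> None:
    """Write transcript records as FASTA wrapped at 60 characters."""
    seq_records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["sample", "time", "event", "group"]
    if list(df.columns[: len(required)]) != required:
        raise ValueError(f"{Path(path).name}: expected columns {required}")
    return df[required]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description/category, then gene symbols)."""
    sets: dict[str, frozenset[str]] = {}
    categories: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{Path(path).name}:{lineno}: fewer than 3 fields")
            name, category, *genes = fields
            if name in sets:
                raise ValueError(f"{Path(path).name}:{lineno}: duplicate set {name!r}")
            sets[name] = frozenset(g for g in genes if g)
            categories[name] = category
    return GeneSetCollection(sets=sets, categories=categories)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in collection.sets.items():
            fh.write(
                "\t".join([name, collection.categories.get(name, "")] + sorted(genes))
                + "\n"
            )
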