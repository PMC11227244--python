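"""Readers and writers for the pipeline's canonical file formats.

Sequences travel as FASTA (via Biopython); every table is TSV with a header
row, UTF-8, and ``.`` for missing values. Readers validate against the
domain-type invariants and reject bad rows instead of coercing.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GeneRecord,
    Lifestyle,
    Role,
    SampleRecord,
    Sex,
    Timepoint,
    Treatment,
    UViGRecord,
    ValidationError,
)

logger = logging.getLogger("phagefmt")

MISSING = "."

ANNOTATION_COLUMNS = [
    "uvig_id",
    "sample_id",
    "viral_genes",
    "host_genes",
    "hallmark_genes",
    "screen_score",
    "completeness_pct",
    "lifestyle",
    "predicted_host",
]

METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "role",
    "treatment",
    "sex",
    "timepoint",
    "donation_round",
]

GENE_COLUMNS = ["gene_id", "uvig_id", "start", "end", "length_bp"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    IDs are the first whitespace-delimited token of the header; sequences
    are upper-cased. Raises :class:`ValidationError` on malformed records.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    with open(path) as handle:
        # reject leading non-header junk that SeqIO would silently skip
        for lineno, line in enumerate(handle, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValidationError(
                    f"{path}: line {lineno}: expected FASTA header, got {line[:30]!r}"
                )
            break
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV dialect

def read_tsv(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def _parse_enum(cls, value: str, row: int, column: str):
    try:
        return cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ValidationError(
            f"row {row}, column {column!r}: unknown value {value!r} (allowed: {allowed})"
        ) from None


# ---------------------------------------------------------------------------
# Metadata

def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata table and validate cohort invariants.

    Rejects duplicate (subject, timepoint) rows for recipients.
    """
    df = read_tsv(path, required=METADATA_COLUMNS)
    records: list[SampleRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        role = _parse_enum(Role, row.role, i, "role")
        treatment = _parse_enum(Treatment, row.treatment, i, "treatment")
        sex = _parse_enum(Sex, row.sex, i, "sex")
        timepoint = _parse_enum(Timepoint, row.timepoint, i, "timepoint")
        round_ = None if pd.isna(row.donation_round) else int(float(row.donation_round))
        rec = SampleRecord(
            sample_id=row.sample_id,
            subject_id=row.subject_id,
            role=role,
            treatment=treatment,
            sex=sex,
            timepoint=timepoint,
            donation_round=round_,
        )
        if role is Role.recipient:
            key = (rec.subject_id, rec.timepoint.value)
            if key in seen:
                raise ValidationError(
                    f"row {i}: duplicate sample for recipient {rec.subject_id} at {rec.timepoint.value}"
                )
            seen.add(key)
        records.append(rec)
    logger.info("read_metadata: %d samples from %s", len(records), path)
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "subject_id": r.subject_id,
            "role": r.role.value,
            "treatment": r.treatment.value,
            "sex": r.sex.value,
            "timepoint": r.timepoint.value,
            "donation_round": r.donation_round,
        }
        for r in records
    ]
    write_tsv(pd.DataFrame(rows, columns=METADATA_COLUMNS), path)


# ---------------------------------------------------------------------------
# Annotations

def read_annotations(
    path: str | Path, sequences: Sequence[tuple[str, str]]
) -> list[UViGRecord]:
    """Join the per-contig annotation table to its FASTA sequences.

    Every annotation row must have a sequence; a missing sequence is an
    error naming the uvig_id.
    """
    seq_of = dict(sequences)
    df = read_tsv(path, required=ANNOTATION_COLUMNS)
    records: list[UViGRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.uvig_id not in seq_of:
            raise ValidationError(f"row {i}: no sequence for uvig_id {row.uvig_id!r}")
        lifestyle = _parse_enum(Lifestyle, row.lifestyle, i, "lifestyle")
        seq = seq_of[row.uvig_id]
        records.append(
            UViGRecord(
                uvig_id=row.uvig_id,
                sample_id=row.sample_id,
                sequence=seq,
                length_bp=len(seq),
                viral_genes=int(row.viral_genes),
                host_genes=int(row.host_genes),
                hallmark_genes=int(row.hallmark_genes),
                screen_score=float(row.screen_score),
                completeness_pct=float(row.completeness_pct),
                lifestyle=lifestyle,
                predicted_host=None if pd.isna(row.predicted_host) else row.predicted_host,
            )
        )
    logger.info("read_annotations: %d UViGs from %s", len(records), path)
    return records


def write_annotations(records: Iterable[UViGRecord], path: str | Path) -> None:
    rows = [
        {
            "uvig_id": r.uvig_id,
            "sample_id": r.sample_id,
            "viral_genes": r.viral_genes,
            "host_genes": r.host_genes,
            "hallmark_genes": r.hallmark_genes,
            "screen_score": r.screen_score,
            "completeness_pct": r.completeness_pct,
            "lifestyle": r.lifestyle.value,
            "predicted_host": r.predicted_host,
        }
        for r in records
    ]
    write_tsv(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS), path)


# ---------------------------------------------------------------------------
# Genes and counts

def read_genes(path: str | Path, uvig_lengths: dict[str, int] | None = None) -> list[GeneRecord]:
    df = read_tsv(path, required=GENE_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = GeneRecord(
            gene_id=row.gene_id,
            uvig_id=row.uvig_id,
            start=int(row.start),
            end=int(row.end),
            length_bp=int(row.length_bp),
        )
        if uvig_lengths is not None:
            parent_len = uvig_lengths.get(rec.uvig_id)
            if parent_len is None:
                raise ValidationError(f"row {i}: unknown parent UViG {rec.uvig_id!r}")
            if rec.end > parent_len:
                raise ValidationError(
                    f"row {i}: gene {rec.gene_id} ends at {rec.end} beyond parent length {parent_len}"
                )
        records.append(rec)
    return records


def write_genes(records: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "uvig_id": g.uvig_id,
            "start": g.start,
            "end": g.end,
            "length_bp": g.length_bp,
        }
        for g in records
    ]
    write_tsv(pd.DataFrame(rows, columns=GENE_COLUMNS), path)


def read_gene_counts(path: str | Path) -> pd.DataFrame:
    """Read a long-format (gene_id, sample_id, count) table into a dense
    gene x sample count matrix (absent combinations are zero)."""
    df = read_tsv(path, required=["gene_id", "sample_id", "count"])
    df["count"] = df["count"].astype(float)
    mat = df.pivot_table(index="gene_id", columns="sample_id", values="count", fill_value=0.0, aggfunc="sum")
    mat.index.name = "gene_id"
    mat.columns.name = "sample_id"
    return mat


def write_gene_counts(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x sample count matrix as sparse long-format TSV
    (zero cells omitted)."""
    long = matrix.stack()
    long = long[long > 0]
    out = long.reset_index()
    out.columns = ["gene_id", "sample_id", "count"]
    write_tsv(out, path)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a dense feature x sample TSV matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t")
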