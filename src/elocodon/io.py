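"""File formats: FASTA coding sequences and tab-separated result tables.

Differential-expression tables are accepted in three column dialects
(DESeq2, edgeR, generic); all tables written by the package use a single
convention — tab-separated, UTF-8, ``.`` decimal separator, missing values
as ``NA`` — so downstream steps parse one dialect only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CodingSequence",
    "read_fasta",
    "write_fasta",
    "read_de_table",
    "write_table",
]

IUPAC_NT = set("ACGTUNRYSWKMBDHV")

DE_COLUMNS = ["gene_id", "base_mean", "lfc", "pvalue", "padj"]

_DIALECTS = {
    "deseq2": {"baseMean": "base_mean", "log2FoldChange": "lfc",
               "pvalue": "pvalue", "padj": "padj"},
    "edger": {"logCPM": "base_mean", "logFC": "lfc",
              "PValue": "pvalue", "FDR": "padj"},
    "generic": {"base_mean": "base_mean", "lfc": "lfc",
                "pvalue": "pvalue", "padj": "padj"},
}


@dataclass(frozen=True)
class CodingSequence:
    """One in-frame coding sequence, identified by a unique gene id."""

    gene_id: str
    sequence: str

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("empty gene_id")
        if len(self.sequence) < 3:
            raise ValueError(f"gene {self.gene_id!r}: sequence shorter than one codon")


def read_fasta(path) -> list[CodingSequence]:
    """Read a multi-record FASTA file of coding sequences.

    The header token up to the first whitespace becomes the gene id;
    multi-line sequences are concatenated and upper-cased.  Duplicate ids
    and non-IUPAC characters raise ``ValueError`` (the latter with the
    offending line number).
    """
    records: list[CodingSequence] = []
    seen: set[str] = set()
    gene_id: str | None = None
    chunks: list[str] = []

    def flush():
        if gene_id is None:
            return
        records.append(CodingSequence(gene_id, "".join(chunks)))

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                gene_id = line[1:].split()[0] if len(line) > 1 else ""
                if not gene_id:
                    raise ValueError(f"{path}: empty FASTA header at line {lineno}")
                if gene_id in seen:
                    raise ValueError(f"{path}: duplicate gene id {gene_id!r}")
                seen.add(gene_id)
                chunks = []
            else:
                if gene_id is None:
                    raise ValueError(f"{path}: sequence before first header (line {lineno})")
                up = line.upper()
                bad = set(up) - IUPAC_NT
                if bad:
                    raise ValueError(
                        f"{path}: non-IUPAC character(s) {sorted(bad)} at line {lineno}"
                    )
                chunks.append(up)
    flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write coding sequences as wrapped FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_de_table(path, dialect: str = "generic", organ: str | None = None) -> pd.DataFrame:
    """Read a differential-expression result table.

    Returns a DataFrame with columns ``gene_id, base_mean, lfc, pvalue,
    padj`` (plus ``organ`` if given).  The gene id comes from a ``gene_id``
    column or, failing that, the first unnamed column.  Rows with missing
    LFC are dropped (count logged); missing p-values are kept as NaN.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    mapping = _DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", na_values=["NA", "NaN", ""])
    missing = [c for c in mapping if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing} for dialect {dialect!r}; "
            f"found {list(df.columns)}"
        )
    if "gene_id" in df.columns:
        ids = df["gene_id"].astype(str)
    else:
        first = df.columns[0]
        if first in mapping:
            raise ValueError(f"{path}: no gene id column found")
        ids = df[first].astype(str)
    out = pd.DataFrame({"gene_id": ids})
    for src, dst in mapping.items():
        col = pd.to_numeric(df[src], errors="coerce")
        bad = col.isna() & df[src].notna() & ~df[src].astype(str).str.upper().isin(["NA", "NAN"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric value in column {src!r} at row {row}")
        out[dst] = col
    n_drop = int(out["lfc"].isna().sum())
    if n_drop:
        log.info("%s: dropped %d row(s) with missing LFC", path, n_drop)
        out = out[out["lfc"].notna()]
    if organ is not None:
        out["organ"] = organ
    dup = out["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate gene id {out['gene_id'][dup].iloc[0]!r}")
    return out.reset_index(drop=True)


def write_table(rows, path) -> None:
    """Write a result table as TSV with ``NA`` for missing values.

    Floats are printed with 12 significant digits so a write/read round
    trip preserves values to that precision; rewriting the same rows gives
    byte-identical output.
    """
    df = pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")
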