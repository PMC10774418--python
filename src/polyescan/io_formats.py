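"""Readers, writers and validated domain types for the plain-text formats
used across the pipeline.

All genomic coordinates are 0-based half-open (BED convention) internally;
1-based inclusive coordinates appear only in human-readable reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 proteinogenic amino acids, one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Accepted residue alphabet: the 20 amino acids plus X for unknown residues.
ALPHABET = frozenset(AMINO_ACIDS + "X")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier.

    The id is the first whitespace-delimited token of the FASTA header; the
    remainder of the header line is kept as ``description``. The sequence is
    uppercase over the 20-letter amino-acid alphabet plus X.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id must be a non-empty token, got {self.id!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: characters outside the amino-acid "
                f"alphabet: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval (BED convention). Strand-agnostic."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotationTable:
    """A gene universe and a term -> gene-set map (e.g. GO-style categories).

    Every annotated gene must be in the universe and empty terms are
    disallowed.
    """

    universe: frozenset[str]
    term_map: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for term, genes in self.term_map.items():
            if not genes:
                raise ValueError(f"term {term!r} annotates zero genes")
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"term {term!r} annotates genes outside the universe: "
                    f"{sorted(stray)[:5]!r}"
                )

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        universe: Iterable[str] | None = None,
    ) -> "AnnotationTable":
        """Build from (gene, term) pairs; universe defaults to all annotated genes."""
        term_map: dict[str, set[str]] = {}
        genes_seen: set[str] = set()
        for gene, term in pairs:
            term_map.setdefault(term, set()).add(gene)
            genes_seen.add(gene)
        uni = frozenset(universe) if universe is not None else frozenset(genes_seen)
        return cls(uni, {t: frozenset(g) for t, g in term_map.items()})

    @property
    def n_terms(self) -> int:
        return len(self.term_map)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, permissive: bool = False) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records.

    Multi-line sequences are concatenated, lowercase residues are uppercased
    and input order is preserved. Duplicate ids and empty sequences raise
    :class:`FormatError`. With ``permissive=True`` residues outside the
    alphabet are mapped to X instead of raising.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if permissive:
            seq = "".join(c if c in ALPHABET else "X" for c in seq)
        desc = rec.description[len(rec.id):].strip()
        try:
            records.append(ProteinRecord(rec.id, seq, desc))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file; extra columns are ignored, input order is kept.

    Malformed lines raise :class:`FormatError` carrying the 1-based line
    number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Generic TSV tables with a typed schema

#: column name -> dtype for the TSV tables consumed by the pipeline
ANNOTATION_SCHEMA: dict[str, type] = {"gene": str, "term": str}
CT_SCHEMA: dict[str, type] = {"target": str, "ct_input": float, "ct_igg": float}
ARRAY_SCHEMA: dict[str, type] = {
    "spot_id": str,
    "modification": str,
    "left_intensity": float,
    "right_intensity": float,
    "is_negative_control": bool,
}
TITRATION_SCHEMA: dict[str, type] = {"concentration": float, "response": float}


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a header-bearing TSV and validate it against ``schema``.

    Missing required columns raise naming the column; non-numeric entries in
    numeric columns raise with the 1-based data-row number; missing values in
    required columns are rejected rather than silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in schema:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = pd.DataFrame(index=df.index)
    for col, typ in schema.items():
        raw = df[col]
        missing = raw.isna() | (raw.str.strip() == "")
        if missing.any():
            row = int(missing.idxmax()) + 1
            raise FormatError(f"{path}: missing value in column {col!r} at data row {row}")
        if typ is float:
            vals = pd.to_numeric(raw, errors="coerce")
            bad = vals.isna()
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise FormatError(
                    f"{path}: non-numeric value {raw[bad.idxmax()]!r} in column "
                    f"{col!r} at data row {row}"
                )
            out[col] = vals.astype(float)
        elif typ is bool:
            lowered = raw.str.strip().str.lower()
            ok = lowered.isin(["true", "false", "1", "0"])
            if not ok.all():
                row = int((~ok).idxmax()) + 1
                raise FormatError(
                    f"{path}: non-boolean value in column {col!r} at data row {row}"
                )
            out[col] = lowered.isin(["true", "1"])
        else:
            out[col] = raw.astype(str)
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), sep="\t", index=False)


def read_annotations(
    path: str | Path, universe: Iterable[str] | None = None
) -> AnnotationTable:
    """Read a gene/term TSV into an :class:`AnnotationTable`."""
    df = read_table(path, ANNOTATION_SCHEMA)
    return AnnotationTable.from_pairs(
        zip(df["gene"], df["term"]), universe=universe
    )
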