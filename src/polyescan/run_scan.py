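"""Detection of maximal homopolymeric amino-acid runs.

A maximal run is a substring of identical residues that cannot be extended
on either side. The screen used throughout the package keeps proteins
carrying at least one run of the target residue (glutamate by default) of a
minimum length (9 by default), mirroring the poly-E motif screen of
glutamate-rich intrinsically disordered regions. Internally runs are 0-based
half-open; reports print 1-based inclusive coordinates, under which
``end - start + 1 == length``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Sequence

from .io_formats import ALPHABET, ProteinRecord

#: Default residue for the poly-E screen.
DEFAULT_RESIDUE = "E"
#: Default minimum tandem run length for a hit.
DEFAULT_MIN_LEN = 9


@dataclass(frozen=True)
class Run:
    """A maximal homopolymeric run: ``sequence[start:end]`` is all ``residue``."""

    residue: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end


@dataclass(frozen=True)
class ScanHit:
    """A protein carrying at least one qualifying run."""

    protein_id: str
    max_run_length: int
    runs: tuple[Run, ...]


def find_runs(sequence: str, residue: str = DEFAULT_RESIDUE, min_len: int = DEFAULT_MIN_LEN) -> list[Run]:
    """All maximal runs of ``residue`` with length >= ``min_len``, left to right.

    The empty sequence yields an empty list. Unknown (X) residues break runs:
    a position not asserted to be the residue never extends one.
    """
    if len(residue) != 1 or residue not in ALPHABET:
        raise ValueError(f"residue must be a single alphabet letter, got {residue!r}")
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    runs: list[Run] = []
    pos = 0
    for letter, group in groupby(sequence):
        n = sum(1 for _ in group)
        if letter == residue and n >= min_len:
            runs.append(Run(residue, pos, pos + n))
        pos += n
    return runs


def max_run_length(sequence: str, residue: str) -> int:
    """Length of the longest run of ``residue`` (0 if absent)."""
    runs = find_runs(sequence, residue, min_len=1)
    return max((r.length for r in runs), default=0)


def scan_proteome(
    records: Sequence[ProteinRecord],
    residue: str = DEFAULT_RESIDUE,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[ScanHit]:
    """Screen a proteome for proteins with >=1 qualifying run.

    Returns one :class:`ScanHit` per qualifying protein, in input order;
    a protein counts once regardless of how many qualifying runs it carries.
    """
    if not records:
        raise ValueError("empty record list")
    hits: list[ScanHit] = []
    for rec in records:
        runs = find_runs(rec.sequence, residue, min_len)
        if runs:
            hits.append(
                ScanHit(
                    protein_id=rec.id,
                    max_run_length=max_run_length(rec.sequence, residue),
                    runs=tuple(runs),
                )
            )
    return hits
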