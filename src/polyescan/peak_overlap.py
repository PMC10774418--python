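"""Coincidence between two genomic peak sets.

Quantifies the fraction of B peaks that share at least ``min_overlap_bp``
bases with the merged A set — e.g. the fraction of damage-marker (γH2AX)
binding sites coincident with a factor's ChIP peaks. Peak calling is out of
scope; the module consumes BED-style interval lists. Strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Sequence

from intervaltree import IntervalTree

from .io_formats import GenomicInterval


@dataclass(frozen=True)
class OverlapResult:
    """Peak-coincidence summary: fraction of B peaks hit by the merged A set."""

    n_a: int
    n_b: int
    n_b_hit: int
    fraction_b_hit: float
    min_overlap_bp: int
    b_hit: tuple[bool, ...]  # per-B-peak hit flag, input order


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Per-chromosome sorted merge of overlapping-or-bookended intervals.

    Total covered base count is preserved.
    """
    merged: list[GenomicInterval] = []
    by_chrom = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    for _, group in groupby(by_chrom, key=lambda iv: iv.chrom):
        current: GenomicInterval | None = None
        for iv in group:
            if current is None:
                current = iv
            elif iv.start <= current.end:  # overlapping or bookended
                if iv.end > current.end:
                    current = GenomicInterval(current.chrom, current.start, iv.end)
            else:
                merged.append(current)
                current = iv
        if current is not None:
            merged.append(current)
    return merged


def overlap_fraction(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> OverlapResult:
    """Fraction of B peaks sharing >= ``min_overlap_bp`` bases with merged A.

    Each B peak is counted once; its shared bases with A are summed over the
    merged (disjoint) A intervals it touches, so a peak spanning two A
    intervals accumulates both.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if not b:
        raise ValueError("empty B set: coincidence fraction is undefined")
    trees: dict[str, IntervalTree] = {}
    for iv in merge_intervals(a):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    hits: list[bool] = []
    for peak in b:
        tree = trees.get(peak.chrom)
        shared = 0
        if tree is not None:
            for hit in tree.overlap(peak.start, peak.end):
                shared += min(peak.end, hit.end) - max(peak.start, hit.begin)
        hits.append(shared >= min_overlap_bp)
    n_hit = sum(hits)
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_b_hit=n_hit,
        fraction_b_hit=n_hit / len(b),
        min_overlap_bp=min_overlap_bp,
        b_hit=tuple(hits),
    )
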