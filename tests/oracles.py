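"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: regex run finding,
exact combinatorial hypergeometric tails, pairwise-count Mann-Whitney U and
per-base bitmap interval coverage.
"""

from __future__ import annotations

import re
from math import comb

import numpy as np


def regex_runs(sequence: str, residue: str, min_len: int) -> list[tuple[int, int]]:
    """(start, end) of maximal runs of ``residue`` with length >= min_len."""
    pattern = re.compile(re.escape(residue) + "+")
    return [
        (m.start(), m.end())
        for m in pattern.finditer(sequence)
        if m.end() - m.start() >= min_len
    ]


def hypergeom_pmf_exact(k: int, K: int, n: int, N: int) -> float:
    """Exact hypergeometric pmf from integer binomials."""
    return comb(K, k) * comb(N - K, n - k) / comb(N, n)


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> float:
    """Exact P[X >= k] by summation over the support."""
    hi = min(n, K)
    return sum(hypergeom_pmf_exact(j, K, n, N) for j in range(k, hi + 1))


def pairwise_u(x, y) -> float:
    """U statistic as the brute-force pairwise count: wins + half ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    wins = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(wins + 0.5 * ties)


def bitmap_coverage(intervals, chrom_len: int) -> np.ndarray:
    """Per-base boolean coverage of one chromosome."""
    cov = np.zeros(chrom_len, dtype=bool)
    for iv in intervals:
        cov[iv.start : iv.end] = True
    return cov


def bitmap_overlap_bp(peak, coverage: np.ndarray) -> int:
    """Bases a peak shares with a coverage bitmap."""
    return int(coverage[peak.start : peak.end].sum())


def random_protein(rng: np.random.Generator, length: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    letters = np.array(list(alphabet))
    return "".join(rng.choice(letters, size=length))
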