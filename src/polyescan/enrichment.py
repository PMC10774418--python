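"""Hypergeometric term enrichment of a gene set against an annotation universe.

For a universe of N genes of which K carry a term, and a query set of n
genes of which k carry it, the enrichment p-value is the hypergeometric
upper tail P[X >= k]. The hit ratio k/n is reported alongside, and
Benjamini-Hochberg q-values are computed over all tested terms (terms with
zero hits cannot be enriched and are not tested).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationTable


@dataclass(frozen=True)
class EnrichmentRow:
    """Per-term hypergeometric enrichment result."""

    term: str
    k: int       # hits: genes in set and term
    n: int       # gene-set size (after dropping genes outside the universe)
    K: int       # term size in universe
    N: int       # universe size
    ratio: float  # k / n
    p_hyper: float
    q_value: float


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    lo, hi = max(0, n + K - N), min(n, K)
    if not (lo <= k <= hi):
        raise ValueError(f"k={k} outside support [{lo}, {hi}] for K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(gene_set: Iterable[str], annotations: AnnotationTable) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of ``gene_set`` over every annotated term.

    Genes outside the universe are dropped with a warning stating how many.
    Rows (one per term with k >= 1) are sorted by ascending p, ties broken
    by term id for determinism.
    """
    genes = set(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    if not annotations.term_map:
        raise ValueError("empty annotation table")
    stray = genes - annotations.universe
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the annotation universe "
            "were dropped",
            stacklevel=2,
        )
        genes -= stray
    if not genes:
        raise ValueError("no query genes remain inside the universe")

    N = len(annotations.universe)
    n = len(genes)
    rows: list[tuple[str, int, int, float]] = []
    for term, members in annotations.term_map.items():
        k = len(genes & members)
        if k == 0:
            continue
        rows.append((term, k, len(members), hypergeom_upper_tail(k, len(members), n, N)))
    if not rows:
        return []
    rows.sort(key=lambda r: (r[3], r[0]))
    qvals = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    return [
        EnrichmentRow(
            term=term, k=k, n=n, K=K, N=N,
            ratio=k / n, p_hyper=p, q_value=float(q),
        )
        for (term, k, K, p), q in zip(rows, qvals)
    ]
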