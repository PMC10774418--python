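"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is deterministic given its seed and returns the generated
data together with a JSON-serializable truth record describing what was
planted, so downstream recovery can be asserted without any external
download. Background protein sequences are i.i.d. per residue (no dipeptide
structure): the scrambling null itself assumes residue exchangeability, so
an i.i.d. background is the matched case. Planted homopolymer runs are
*inserted* (the sequence is lengthened), not overwritten, leaving the
background composition untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AMINO_ACIDS, AnnotationTable, GenomicInterval, ProteinRecord

#: Residue order used by composition vectors: the 20 amino acids then X.
ALPHABET_ORDER = AMINO_ACIDS + "X"

IntSampler = Callable[[np.random.Generator, int], np.ndarray]


def fixed_sampler(value: int) -> IntSampler:
    """Sampler returning a constant integer."""
    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, value, dtype=np.int64)
    return sample


def uniform_int_sampler(low: int, high: int) -> IntSampler:
    """Sampler uniform on the inclusive integer range [low, high]."""
    if high < low:
        raise ValueError("high < low")
    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.integers(low, high + 1, size=size)
    return sample


def composition(overrides: Mapping[str, float] | None = None) -> np.ndarray:
    """Residue probability vector over :data:`ALPHABET_ORDER`.

    Residues named in ``overrides`` get the stated frequency; the remaining
    mass is shared uniformly over the other 20 amino acids (X stays at 0
    unless overridden).
    """
    overrides = dict(overrides or {})
    p = np.zeros(len(ALPHABET_ORDER))
    fixed_mass = 0.0
    free: list[int] = []
    for i, letter in enumerate(ALPHABET_ORDER):
        if letter in overrides:
            p[i] = overrides[letter]
            fixed_mass += overrides[letter]
        elif letter != "X":
            free.append(i)
    if fixed_mass > 1.0 + 1e-9:
        raise ValueError(f"override frequencies sum to {fixed_mass} > 1")
    if free:
        p[free] = (1.0 - fixed_mass) / len(free)
    return p


# ---------------------------------------------------------------------------
# Proteomes


@dataclass
class ProteomeSpec:
    """Background proteome with optional planted homopolymer runs.

    ``planted_runs`` is a list of (residue, run_length, n_carriers): for each
    entry, exactly ``n_carriers`` sequences receive one inserted exact run of
    ``run_length`` residues at a uniformly chosen internal position.
    """

    n_sequences: int
    length_sampler: IntSampler = field(default_factory=lambda: fixed_sampler(500))
    composition: np.ndarray = field(default_factory=composition)
    planted_runs: Sequence[tuple[str, int, int]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.composition.shape != (len(ALPHABET_ORDER),):
            raise ValueError(
                f"composition must have {len(ALPHABET_ORDER)} entries "
                f"(order {ALPHABET_ORDER!r})"
            )
        if np.any(self.composition < 0) or abs(self.composition.sum() - 1.0) > 1e-9:
            raise ValueError("composition must be non-negative and sum to 1 +/- 1e-9")
        for residue, run_length, n_carriers in self.planted_runs:
            if residue not in ALPHABET_ORDER:
                raise ValueError(f"unknown residue {residue!r}")
            if run_length < 1:
                raise ValueError("run_length must be >= 1")
            if not (0 <= n_carriers <= self.n_sequences):
                raise ValueError("n_carriers must be between 0 and n_sequences")


def gen_proteome(spec: ProteomeSpec) -> tuple[list[ProteinRecord], dict]:
    """Generate a background proteome with planted runs; returns (records, truth)."""
    rng = np.random.default_rng(spec.seed)
    lengths = np.asarray(spec.length_sampler(rng, spec.n_sequences), dtype=np.int64)
    if np.any(lengths < 30):
        raise ValueError("length_sampler must produce lengths >= 30")
    letters = np.frombuffer(ALPHABET_ORDER.encode("ascii"), dtype=np.uint8)
    seqs: list[str] = []
    for length in lengths:
        idx = rng.choice(len(letters), size=int(length), p=spec.composition)
        seqs.append(letters[idx].tobytes().decode("ascii"))

    truth_runs: list[dict] = []
    for residue, run_length, n_carriers in spec.planted_runs:
        carriers = rng.choice(spec.n_sequences, size=n_carriers, replace=False)
        for i in carriers:
            if run_length > len(seqs[i]):
                raise ValueError(
                    f"planted run of {run_length} longer than sequence of "
                    f"{len(seqs[i])}"
                )
            pos = int(rng.integers(1, len(seqs[i])))  # strictly internal
            seqs[i] = seqs[i][:pos] + residue * run_length + seqs[i][pos:]
        truth_runs.append({
            "residue": residue,
            "run_length": int(run_length),
            "carrier_ids": sorted(f"syn{int(i):05d}" for i in carriers),
        })
    records = [ProteinRecord(f"syn{i:05d}", seq) for i, seq in enumerate(seqs)]
    truth = {"seed": spec.seed, "n_sequences": spec.n_sequences,
             "planted_runs": truth_runs}
    return records, truth


# ---------------------------------------------------------------------------
# Peak-set pairs


@dataclass
class PeakPairSpec:
    """Two peak sets with an exact planted coincidence fraction.

    ``round(coincidence_fraction * n_b)`` B peaks are placed to overlap an A
    peak by at least one base; every remaining B peak overlaps no A peak.
    """

    chrom_sizes: Mapping[str, int]
    n_a: int
    n_b: int
    coincidence_fraction: float
    width_sampler: IntSampler = field(default_factory=lambda: uniform_int_sampler(200, 400))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must be non-empty")
        if any(size <= 0 for size in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be positive")
        if self.n_a < 0 or self.n_b < 1:
            raise ValueError("need n_a >= 0 and n_b >= 1")
        if not (0.0 <= self.coincidence_fraction <= 1.0):
            raise ValueError("coincidence_fraction must be in [0, 1]")


def gen_peak_pair(
    spec: PeakPairSpec,
) -> tuple[list[GenomicInterval], list[GenomicInterval], dict]:
    """Generate (A peaks, B peaks, truth) with exact planted coincidence."""
    rng = np.random.default_rng(spec.seed)
    n_hit = int(round(spec.coincidence_fraction * spec.n_b))
    if n_hit > 0 and spec.n_a == 0:
        raise ValueError("cannot plant coincident B peaks with n_a = 0")
    widths_a = spec.width_sampler(rng, spec.n_a)
    widths_b = spec.width_sampler(rng, spec.n_b)

    # units: an A peak (optionally carrying hit-B peaks) or a lone miss-B peak
    units: list[dict] = [{"a_width": int(w), "b_widths": []} for w in widths_a]
    for j in range(n_hit):
        units[j % spec.n_a]["b_widths"].append(int(widths_b[j]))
    units.extend({"a_width": None, "b_widths": [int(w)]}
                 for w in widths_b[n_hit:])
    rng.shuffle(units)

    chroms = list(spec.chrom_sizes.items())
    a_peaks: list[GenomicInterval] = []
    b_peaks: list[GenomicInterval] = []
    chrom_idx = 0
    cursor = 0
    for unit in units:
        # lay the unit out at a relative origin first
        gap = int(rng.integers(20, 200))
        if unit["a_width"] is not None:
            wa = unit["a_width"]
            placements = [("A", 0, wa)]
            for wb in unit["b_widths"]:
                offset = int(rng.integers(0, wa))  # guarantees >=1 bp overlap
                placements.append(("B", offset, offset + wb))
        else:
            wb = unit["b_widths"][0]
            placements = [("B", 0, wb)]
        extent = max(end for _, _, end in placements)

        while chrom_idx < len(chroms) and cursor + gap + extent > chroms[chrom_idx][1]:
            chrom_idx += 1
            cursor = 0
        if chrom_idx >= len(chroms):
            raise ValueError("chromosomes too crowded to place all peaks")
        chrom = chroms[chrom_idx][0]
        origin = cursor + gap
        for kind, start, end in placements:
            iv = GenomicInterval(chrom, origin + start, origin + end)
            (a_peaks if kind == "A" else b_peaks).append(iv)
        cursor = origin + extent

    truth = {
        "seed": spec.seed,
        "n_a": spec.n_a,
        "n_b": spec.n_b,
        "n_b_coincident": n_hit,
        "coincidence_fraction": n_hit / spec.n_b,
    }
    return a_peaks, b_peaks, truth


# ---------------------------------------------------------------------------
# Titrations


def isotherm(c: np.ndarray | float, kd: float, amplitude: float, baseline: float):
    """Noise-free 1:1 binding isotherm, ``baseline + amplitude * c / (kd + c)``."""
    c = np.asarray(c, dtype=float)
    return baseline + amplitude * c / (kd + c)


@dataclass
class TitrationSpec:
    """A 1:1 binding titration with Gaussian noise.

    The amplitude's sign encodes the response directionality (an inverted
    thermophoresis signal is a negative amplitude). Concentrations must
    number at least 6 and span at least two orders of magnitude for the Kd
    to be identifiable.
    """

    kd: float
    amplitude: float = 1.0
    baseline: float = 0.0
    concentrations: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.05, 1000.0, 12)
    )
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        c = self.concentrations
        if len(c) < 6:
            raise ValueError("need at least 6 concentrations")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if c.max() / c.min() < 100.0:
            raise ValueError("concentrations must span >= 2 orders of magnitude")


def gen_titration(spec: TitrationSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a concentration/response table; returns (table, truth)."""
    rng = np.random.default_rng(spec.seed)
    y = isotherm(spec.concentrations, spec.kd, spec.amplitude, spec.baseline)
    y = y + rng.normal(0.0, spec.noise_sd, size=len(spec.concentrations))
    table = pd.DataFrame({"concentration": spec.concentrations, "response": y})
    truth = {"seed": spec.seed, "kd": spec.kd, "amplitude": spec.amplitude,
             "baseline": spec.baseline, "noise_sd": spec.noise_sd}
    return table, truth


# ---------------------------------------------------------------------------
# Annotation universes


def gen_annotations(
    universe_size: int,
    n_terms: int,
    term_size_sampler: IntSampler,
    planted: tuple[str, Sequence[str], int] | None = None,
    seed: int = 0,
    gene_names: Sequence[str] | None = None,
) -> tuple[AnnotationTable, dict]:
    """Random term -> gene annotations with one optionally planted term.

    ``gene_names`` overrides the default ``g00000``-style universe naming
    (it must have ``universe_size`` entries), so the universe can be made of
    protein ids from a generated proteome.

    ``planted = (term, gene_set, excess)``: the named term is forced to
    contain ``excess`` genes drawn from ``gene_set`` on top of a uniform
    draw of the rest of its size from the remaining universe. With
    ``excess=0`` the planted term is indistinguishable from random
    assignment, so its hit count in ``gene_set`` follows the hypergeometric
    null exactly.
    """
    if universe_size < 1 or n_terms < 1:
        raise ValueError("universe_size and n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    if gene_names is not None:
        if len(gene_names) != universe_size:
            raise ValueError("gene_names must have universe_size entries")
        if len(set(gene_names)) != len(gene_names):
            raise ValueError("gene_names must be unique")
        genes = np.array(list(gene_names))
    else:
        genes = np.array([f"g{i:05d}" for i in range(universe_size)])
    sizes = np.asarray(term_size_sampler(rng, n_terms), dtype=np.int64)
    if np.any(sizes < 1) or np.any(sizes > universe_size):
        raise ValueError("term sizes must be in [1, universe_size]")

    term_map: dict[str, frozenset[str]] = {}
    for t, size in enumerate(sizes):
        members = rng.choice(universe_size, size=int(size), replace=False)
        term_map[f"T{t:03d}"] = frozenset(genes[members])

    truth: dict = {"seed": seed, "universe_size": universe_size, "n_terms": n_terms}
    if planted is not None:
        term, gene_set, excess = planted
        gene_set = list(dict.fromkeys(gene_set))
        universe_set = set(genes)
        if not set(gene_set) <= universe_set:
            raise ValueError("planted gene_set must be a subset of the universe")
        size = int(term_size_sampler(rng, 1)[0])
        if size > universe_size:
            raise ValueError("planted term size exceeds universe")
        if excess > min(size, len(gene_set)):
            raise ValueError("excess exceeds planted term size or gene_set size")
        forced = list(rng.choice(gene_set, size=excess, replace=False)) if excess else []
        remaining_pool = np.array(sorted(universe_set - set(forced)))
        rest = rng.choice(remaining_pool, size=size - excess, replace=False)
        term_map[term] = frozenset(forced) | frozenset(rest)
        truth.update({
            "planted_term": term,
            "excess": int(excess),
            "planted_term_size": size,
            "planted_gene_set": sorted(gene_set),
        })
    table = AnnotationTable(frozenset(genes), term_map)
    return table, truth


# ---------------------------------------------------------------------------
# Duplicate-spot arrays


def noise_sd_for_duplicate_r2(means: np.ndarray, target_r2: float) -> float:
    """Duplicate noise SD giving an expected left/right Pearson R^2.

    For left = m + e1 and right = m + e2 with independent noise of variance
    s^2, the Pearson correlation is r = var(m) / (var(m) + s^2); solve for s
    at r = sqrt(target_r2).
    """
    if not (0.0 < target_r2 < 1.0):
        raise ValueError("target_r2 must be in (0, 1)")
    var_m = float(np.var(means))
    r = math.sqrt(target_r2)
    return math.sqrt(var_m * (1.0 - r) / r)


def gen_array_table(
    n_modifications: int,
    binder_set: Sequence[str] = (),
    duplicate_noise_sd: float | None = None,
    seed: int = 0,
    n_negative_controls: int = 8,
    background_mean: float = 1000.0,
    background_sd: float = 150.0,
    binder_fold: float = 5.0,
    target_duplicate_r2: float = 0.927,
) -> tuple[pd.DataFrame, dict]:
    """Duplicate-spot array intensities; returns (table, truth).

    Modifications are named ``mod000`` ... Binder spots receive
    ``binder_fold`` times the background mean; left/right duplicates share a
    spot mean plus independent Gaussian noise. When ``duplicate_noise_sd``
    is None it is derived from ``target_duplicate_r2`` (default 0.927, the
    duplicate concordance the generator emulates).
    """
    if n_modifications < 1:
        raise ValueError("n_modifications must be >= 1")
    mods = [f"mod{i:03d}" for i in range(n_modifications)]
    binders = set(binder_set)
    if not binders <= set(mods):
        raise ValueError("binder_set must be a subset of the modification names")
    rng = np.random.default_rng(seed)
    means = rng.normal(background_mean, background_sd, size=n_modifications)
    means = np.clip(means, background_mean * 0.1, None)
    for i, mod in enumerate(mods):
        if mod in binders:
            means[i] *= binder_fold
    neg_means = np.full(n_negative_controls, background_mean)
    all_means = np.concatenate([means, neg_means])
    if duplicate_noise_sd is None:
        duplicate_noise_sd = noise_sd_for_duplicate_r2(all_means, target_duplicate_r2)
    noise = rng.normal(0.0, duplicate_noise_sd, size=(len(all_means), 2))
    rows = []
    for i, mod in enumerate(mods):
        rows.append((f"s{i:04d}", mod, all_means[i] + noise[i, 0],
                     all_means[i] + noise[i, 1], False))
    for j in range(n_negative_controls):
        i = n_modifications + j
        rows.append((f"s{i:04d}", f"neg{j:03d}", all_means[i] + noise[i, 0],
                     all_means[i] + noise[i, 1], True))
    table = pd.DataFrame(
        rows,
        columns=["spot_id", "modification", "left_intensity", "right_intensity",
                 "is_negative_control"],
    )
    truth = {
        "seed": seed,
        "binders": sorted(binders),
        "duplicate_noise_sd": float(duplicate_noise_sd),
        "spot_means": {m: float(v) for m, v in zip(mods, means)},
    }
    return table, truth
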