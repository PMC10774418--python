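# Methods

`polyescan` re-implements, as a tested pipeline, the computational analyses
that accompany a study of a glutamate-rich intrinsically disordered region:
mining a proteome for homopolymeric amino-acid runs, testing run-length
enrichment against a sequence-scrambling permutation null, hypergeometric
term enrichment of the hit set, ChIP-seq peak coincidence, and the standard
quantification models for the supporting assays (ChIP-qPCR fold
enrichment, duplicate-spot array scoring, and a 1:1 binding-isotherm Kd
fit). This note records the models, the defaults and why they were chosen,
and the limits of what the synthetic-data tests demonstrate.

## Homopolymer run scan

A *maximal run* is a substring of identical residues that cannot be
extended on either side. `run_scan.find_runs` reports all maximal runs of a
target residue at or above a threshold; `scan_proteome` keeps proteins with
at least one qualifying run, counting each protein once regardless of run
multiplicity. Defaults are residue `E` and minimum length 9 — the poly-E
screen for glutamate-rich IDR motifs. The original mining used a BLASTP
database search; here the motif is an exact tandem repeat, so exact
scanning over a supplied FASTA is the well-defined core and the
database-retrieval step is out of scope. Two deliberate choices:

* Only exact tandem runs count; near-runs with single interruptions do not.
* `X` (unknown residue) breaks runs: an unassigned position is never
  asserted to be the target residue.

Internally coordinates are 0-based half-open; reports print 1-based
inclusive coordinates, under which `end − start + 1 = length` (a 9-residue
run spanning aa 272–280 in the 1-based convention).

Note on nomenclature: one written description of the original screen says
"glutamine" where the surrounding analysis clearly concerns glutamate (E).
The scan is residue-parametric, so either reading is a parameter choice;
the default is E.

## Scrambling permutation null

To ask whether long runs occur more often than composition alone predicts,
each hit sequence is independently shuffled (a uniform permutation of its
residues — per-sequence length and composition are preserved exactly), and
the pooled multiset of maximal run lengths (default: segments of length
≥ 2, since a single residue is not a repeat) is extracted from `n_scrambles
= 100` scrambles. The observed pooled run lengths are compared against the
scrambled pool with a one-sided Mann–Whitney U test (alternative: observed
stochastically larger).

Statistical choices:

* **Pooling, not averaging.** "The average length distribution" of
  scrambles is not a sample a rank test can consume; the null sample is the
  pool of run lengths across all scrambles, with the per-scramble run
  counts reported separately as the average-distribution summary. As the
  number of scrambles grows, the pooled empirical distribution converges to
  the same null law.
* **Normal approximation with tie correction and continuity correction,
  always.** Run lengths are heavily tied small integers; the tie-corrected
  variance is mandatory, and exact U enumeration is infeasible at the
  sample sizes where the test matters. The asymptotic path of
  `scipy.stats.mannwhitneyu` implements exactly this formulation; a
  z-score and log10 p are additionally computed in-module from the same
  formula so that p-values below double-precision underflow remain
  reportable. Two fully tied samples have zero variance and return p = 1.
* The test is deterministic given a seed, and the U statistic equals the
  brute-force pairwise count (wins + ½·ties), which the tests assert.

Calibration is checked by simulation: background-only proteomes (148
sequences × 500 aa, E at 7%) tested against their own scrambles reject at
the nominal 5% level (measured band 1–12% over 100 replicates); proteomes
in which every sequence carries one planted 9-E run over a 2% E background
give one-sided p far below 1e-10, the desk-scale analogue of the original
"p < 1e-70" direction.

## Hypergeometric enrichment

For a universe of `N` genes, a term annotating `K` of them, and a query set
of `n` genes with `k` hits, the enrichment p-value is the upper tail
`P[X ≥ k]`, `X ~ Hypergeometric(N, K, n)` (computed via `scipy`; tests
verify it against exact integer enumeration to 1e-12 for all parameter
combinations with N ≤ 30). The hit ratio `k/n` is reported alongside, as in
the original per-category "hits / 148 poly-E proteins" panels. Terms with
zero hits cannot be enriched and are not tested; Benjamini–Hochberg
q-values are computed over the tested family — genome-wide term testing
without any adjustment is indefensible, so q-values are added even though
the analysis being mirrored reported raw significance. The universe is a
required user input; no default gene catalogue is assumed. External
annotation-clustering composite scores (e.g. DAVID's) are out of scope.

## Peak coincidence

`overlap_fraction(a, b)` merges the A peaks per chromosome
(overlapping-or-bookended intervals are unioned) and counts a B peak as hit
when it shares at least `min_overlap_bp` bases (default 1) with the merged
A set, summed across the disjoint A intervals it touches. The reported
statistic is the fraction of B peaks hit — matching the "fraction of
damage-marker binding sites coincident with factor peaks" convention, with
the B set as denominator; the CLI offers an A-denominator mode. Strand is
ignored and peak calling is out of scope. The implementation uses an
interval tree and is verified against a per-base bitmap oracle. Because the
original coincidence figure depends on peak sets derived from deposited raw
data by unstated peak calling, it is not recomputable from published
information; the pipeline instead proves exactness on generated pairs with
a planted coincidence fraction.

## Assay quantification

* **ChIP-qPCR.** `fold_enrichment` implements the printed formula
  literally: fold = 2^(−ΔCt) with ΔCt = Ct_input − Ct_IgG. This omits the
  specific-antibody Ct, which conventional ChIP analysis uses; whether that
  is intentional cannot be decided from the text, so the literal formula is
  the default and `percent_of_input` provides the conventional
  percent-of-input alternative, clearly separated.
* **Arrays.** Per-modification binding score = mean of the modification's
  duplicate intensities over the mean of all negative-control intensities;
  duplicate concordance = squared Pearson correlation of (left, right)
  spot pairs, which is affine-invariant by construction.
* **Binding isotherm.** Titrations are fit to the 1:1 Langmuir isotherm
  `response = baseline + amplitude·c/(Kd + c)` by least squares. The
  instrument software that produced the original Kd values does not
  publish its model; the 1:1 isotherm without ligand depletion (labeled
  partner far below Kd) is the minimal standard choice. Kd positivity is
  enforced by optimizing log Kd; baseline and amplitude are profiled out
  linearly at each candidate Kd, a 60-point log-spaced multi-start grid
  spanning two decades beyond the sampled concentrations guards against
  local minima, and a bounded scalar refinement polishes the optimum. The
  amplitude's sign is free: an inverted response direction is fit exactly
  as well as a positive one. "No binding / n.d." is operationalized as an
  F-test of the isotherm against the flat-line model (2 extra parameters,
  default α = 0.05): a fixed fractional-RSS threshold would misclassify
  either pure noise or shallow real binding depending on n, while the
  F-test controls the false-binding rate. The Kd confidence interval is a
  profile interval from the F threshold on the RSS ratio, with crossings
  refined by root finding.

## Synthetic data: what it does and does not show

All generators live in `polyescan.synthetic`, are deterministic given their
seed, and return a JSON-serializable truth record alongside the data (the
CLI writes it as a `.truth.json` sidecar).

* **Proteomes** are i.i.d. per-residue draws from a configurable
  composition; planted runs are inserted at a uniform internal position,
  lengthening the sequence rather than overwriting background. Real
  proteins have dipeptide structure, domain composition biases and shared
  evolutionary history that i.i.d. backgrounds lack; since the scrambling
  null itself assumes residue exchangeability, the i.i.d. background is the
  matched (null-true) case for calibration, and passing tests do not show
  that real proteomes satisfy exchangeability.
* **Peak pairs** are constructed, not sampled: exactly
  `round(f · n_b)` B peaks overlap an A peak by ≥ 1 bp and the rest
  overlap none, so the planted fraction is recovered exactly. Real peak
  sets have width/score distributions and genomic clustering this does not
  emulate.
* **Titrations** use homoscedastic Gaussian noise on the isotherm. Default
  design: 12 points log-spaced over 0.05–1000 concentration units, which
  spans both the strong (2.4) and weak (64) binder regimes of the Kd
  contrast the tests exercise; noise default 0.05 (5% of the unit
  amplitude). At that noise and 12 points, the Fisher information bounds
  the relative standard error of any Kd estimator at ≳ 12–17% for
  realistic designs, so single-titration Kd estimates at 5% noise carry
  errors of that order — a property of the experiment, not of the fitter
  (the noiseless fit recovers Kd to 1e-6 relative error).
* **Annotation universes** assign term members uniformly without
  replacement; the planted term forces `excess` genes from the target set
  on top of a uniform draw of the rest, so `excess = 0` reduces exactly to
  random assignment and the planted hit count follows the hypergeometric
  null by construction. Recovery tests plant `excess = 15` over a
  148-gene set in a universe of 2,000 with 50 terms of 20–60 genes.
* **Arrays** give binder modifications a 5-fold elevated mean over a
  background of 1000 ± 150 intensity units; left/right duplicates share the
  spot mean plus independent Gaussian noise. The default noise is derived
  analytically from a target duplicate R² of 0.927 — the duplicate
  concordance the generator emulates — via
  r = var(means)/(var(means) + σ²).

## Problem sizes and numerical conventions

The simulation scales used throughout the tests and the acceptance script —
148-sequence hit sets of 500-aa proteins, 100 scrambles, 100-replicate
calibration and recovery loops, 2,000-peak B sets, 100-seed Kd recovery —
are the study-scale defaults of the package. Reports avoid timestamps and
hostnames so identical configs and seeds reproduce outputs byte-identically;
random streams are `numpy` `default_rng` generators seeded explicitly, with
sub-seeds drawn from a master generator where one run needs several
streams. Degenerate inputs raise rather than guess: empty B peak sets
(undefined fraction), empty observed run-length distributions, empty gene
sets, non-positive negative-control means, sub-4-point titrations.

## Known limitations

* The scan handles single-residue motifs only; multi-residue repeats and
  interrupted ("near-run") motifs are out of scope.
* The scrambling null shuffles within sequences; composition-stratified or
  dipeptide-preserving shuffles are not implemented.
* Enrichment does not propagate ontology ancestors; annotations are taken
  as given.
* The isotherm fit does not model ligand depletion or instrument-specific
  signal physics.
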