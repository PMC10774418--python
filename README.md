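# polyescan

Homopolymeric amino-acid runs — poly-glutamate (poly-E) tracts in
particular — are a recurring feature of intrinsically disordered regions
that mediate chromatin and histone interactions. `polyescan` is a small
analysis toolkit for the computational questions that come up around such a
motif:

* **How many proteins carry it?** Scan a proteome FASTA for maximal runs
  of a residue at or above a length threshold (default: ≥ 9 tandem E).
* **Is it more than composition predicts?** Compare the observed run-length
  distribution of the hit set against a *sequence-scrambling permutation
  null* — each protein uniformly shuffled, preserving its length and
  composition — with a one-sided Mann–Whitney U test (midranks,
  tie-corrected variance, continuity correction).
* **What are the hits enriched for?** Hypergeometric upper-tail enrichment
  `P[X ≥ k]`, `X ~ Hypergeom(N, K, n)`, of the hit set over an annotation
  universe, with hit ratios `k/n` and Benjamini–Hochberg q-values.
* **Do two ChIP-seq peak sets coincide?** The fraction of B peaks sharing
  ≥ m bases with the merged A set (interval-tree implementation, BED
  conventions).
* **Assay quantification.** ChIP-qPCR fold enrichment `2^(−ΔCt)`
  (ΔCt = Ct_input − Ct_IgG), duplicate-spot array binding scores with
  left/right concordance R², and a 1:1 binding-isotherm fit
  `y = baseline + A·c/(Kd + c)` with a profile confidence interval and a
  principled "no binding / n.d." call.

Every input the pipeline consumes can be simulated with planted ground
truth (`polyescan.synthetic` / `polyescan simulate …`), so the whole
analysis is testable end to end with no downloads.

## Worked example

Simulate a 500-protein background proteome (2% glutamate) in which 60
proteins carry one planted 9-E run, then run the full scan → scrambling
null → report pipeline:

```bash
polyescan simulate proteome --n-sequences 500 --n-carriers 60 \
    --residue-freq 0.02 --seed 7 --out proteome.fa
polyescan run-all --fasta proteome.fa --out-dir results --n-scrambles 100 --seed 7
```

```
hits: 60/500
scramble null: p=1.49e-242 (log10 p = -241.8)
```

The scan recovers exactly the 60 planted carriers (`results/hits.tsv`
lists each run with 1-based coordinates), and the observed run lengths are
astronomically longer than the pooled lengths from 100 composition-
preserving scrambles — the planted poly-E tracts could not have arisen from
these sequences' compositions by chance. `results/report.json` embeds all
parameters, the seed and input checksums; rerunning the same command
reproduces it byte-identically.

Peak coincidence on a simulated pair with a planted 14% overlap:

```bash
polyescan simulate peaks --n-a 1000 --n-b 2000 --coincidence 0.14 --seed 7 \
    --out-a cyclin_d1.bed --out-b gh2ax.bed
polyescan overlap --a cyclin_d1.bed --b gh2ax.bed --out overlap.json
```

```
280/2000 = 0.1400
```

exactly the planted fraction: 280 of the 2,000 B peaks share at least one
base with an A peak.

Kd estimation from a noisy 12-point titration of a strong binder
(true Kd = 2.4 concentration units, 5% noise):

```bash
polyescan simulate titration --kd 2.4 --noise-sd 0.05 --seed 7 --out titration.tsv
polyescan quant kd --table titration.tsv --out kd.json
```

```
Kd = 2.827 (CI 2.21 - 3.61)
```

The point estimate is ~18% off and the 95% profile interval brackets the
truth — representative of the precision a single 12-point titration at 5%
noise can deliver (see `docs/methods.md` on the information limit).

The same functionality is available as a library:

```python
from polyescan import ProteomeSpec, composition, gen_proteome, scan_proteome

records, truth = gen_proteome(ProteomeSpec(
    n_sequences=500, composition=composition({"E": 0.02}),
    planted_runs=[("E", 9, 60)], seed=7))
hits = scan_proteome(records, residue="E", min_len=9)   # 60 ScanHits
```

## Layout

| Module | Purpose |
| --- | --- |
| `polyescan.io_formats` | FASTA / BED3 / schema-validated TSV readers and writers, domain types |
| `polyescan.run_scan` | maximal homopolymer run detection and proteome screening |
| `polyescan.scramble_null` | scrambling permutation null + Mann–Whitney U |
| `polyescan.enrichment` | hypergeometric term enrichment with BH q-values |
| `polyescan.peak_overlap` | interval merging and peak-coincidence fractions |
| `polyescan.assay_quant` | ΔCt fold enrichment, array scores, isotherm Kd fit |
| `polyescan.synthetic` | seeded generators with planted-truth sidecars |
| `polyescan.pipeline`, `polyescan.cli` | `run-all` orchestration and the `polyescan` CLI |

See `docs/methods.md` for the models, defaults and their rationale.
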