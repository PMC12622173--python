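# Methods

This note documents the models, statistics, defaults and numerical choices
behind `regnet`, and what the synthetic benchmarks do and do not show.

## Coordinates and peak processing

All intervals are 0-based half-open (BED convention) end to end; merging
treats half-open abutting intervals (`[100,200)`, `[200,300)`) as separate.
`merge_peaks` collapses any transitive chain of ≥ 1 bp overlaps into its
bounding interval and assigns fresh `merged_<k>` ids; tag counts are
deliberately dropped because merged intervals must be re-annotated against
the samples.

Replicate selection maximizes Pearson correlation of log2(tag count + 1)
across peaks over all sample pairs (ties broken lexicographically).
Counts are used raw (no length or depth normalization) at this step; the
choice is documented rather than hidden because correlation rankings are
usually insensitive to a common scale factor. A pair containing a constant
count vector has undefined correlation and is scored −∞ with a warning.

Peak-to-gene annotation measures from the peak midpoint
`floor((start+end)/2)` to the nearest TSS; the sign is positive downstream
of the TSS on the gene's strand. Classes follow the conventional bands:
**proximal** |d| < 500 bp, **distal** |d| > 1000 bp, and an explicit
**intermediate** class for the 500–1000 bp band rather than a silent
assignment. Nearest-gene ties at equal distance resolve alphabetically.
Reproducibility filtering across replicates is intentionally simple
(selection of the best-correlated pair; no irreproducible-discovery-rate
model) — a documented stand-in, isolated from the statistics downstream.

## Differential peak test (a documented stand-in)

Real studies use a negative-binomial GLM with shared dispersion estimation
(DESeq2-class machinery). Re-implementing that is out of scope here;
instead:

- low-signal filter: keep a peak if its **maximum** raw count across
  samples is ≥ `min_tag_count` (default 4);
- depth normalization: scale each sample column so its sum equals the
  median raw column sum. This assumes differential signal is a modest,
  roughly balanced fraction of peaks — a strongly one-sided signal on a
  large fraction of peaks biases the scale factors (the classic argument
  for median-of-ratios normalization), which is why the demo plants
  two-sided fold changes on ~13% of peaks;
- effect size: `log2((mean_B + 1)/(mean_A + 1))` on normalized counts;
  the pseudocount of 1 bounds log-ratios at zero counts;
- significance: two-sided Welch t-test on log2(normalized count + 1), BH
  adjustment across retained peaks; a peak with zero variance and equal
  means in both groups gets p = 1;
- calls: `up_in_b` / `down_in_b` require |log2FC| > log2(`fc_threshold`)
  (default FC 2) **and** padj < `alpha` (default 0.05), applied to the raw
  pseudocounted log-ratio (not a shrunken estimate).

The stand-in is validated by simulation only: on all-null NB tables
(500 peaks, 4 vs 4, mean 100) the fraction of peaks at padj < 0.05 is far
below 5%, and planted |log2FC| = 3 peaks are detected ≥ 95% of the time.
With four replicates per group a Welch test is underpowered for a solitary
differential peak (a single discovery carries the whole BH penalty); the
calibration experiments therefore plant 20 of 500 peaks, the regime the
test is meant for.

## PWM scanning and motif enrichment

PWMs carry a pseudocount of 0.01 per cell (rows renormalized) so no cell is
zero and scores stay finite. Scores are log2-odds in bits:
`sum_j log2(p_motif(j, base) / p_background(base))`, computed on both
strands (reverse-strand hits reported in forward coordinates). Windows
containing N are skipped. When a motif library provides no threshold, the
default is 80% of the motif's maximum attainable score under a uniform
background; HOMER-format header thresholds are honored numerically on this
bits scale (HOMER's own natural-log convention is not re-derived). Note a
consequence of pseudocounting sharp consensus motifs: an occurrence sampled
from the PWM passes the 80% threshold only when it matches the consensus
exactly, so per-planted-hit detection is ≈ p_consensus^L (~0.73–0.78 for
the 8-mers used in the benchmarks). Recovery claims below already include
this loss.

Non-overlapping resolution is greedy by descending score (ties: leftmost
offset, then + strand, then motif id); a hit is kept iff its span overlaps
no previously kept span, regardless of motif identity — at most one motif
call per base.

Enrichment is at **peak level** (a peak counts once however many hits it
has), matching the target/background-percentage convention of known-motif
enrichment tools. Background sequences are random i.i.d. sequences matched
to the target set's GC (snapped to 2%-wide bins) and length distributions,
targets cycled round-robin (so equal counts reproduce the length multiset
exactly); default background size is twice the target count. The p-value
is the exact binomial upper tail `P(X ≥ k_target)` with
`X ~ Binomial(n_target, f_bg)` and `f_bg = max(k_bg, 0.5)/n_bg` (floored to
avoid zero). `log_p` is natural log; reports display −log10 p.

## Co-occurrence network and cliques

The unit of co-occurrence is peak-level presence (≥ 1 resolved hit) on the
active-enhancer set, optionally restricted to an expressed-TF motif
whitelist. Each unordered motif pair is tested with a **one-sided Fisher
exact test** (hypergeometric tail) on the 2×2 presence table — exact under
the marginals-fixed null and standard for co-occurrence; whether the null
should instead condition on per-peak motif density is an open modelling
question, and presence-level Fisher is this package's documented reading.
Edges are kept at raw p < 0.001 (no multiple-testing correction by
default, matching the fixed-threshold convention; BH across pairs is
available as an option). Odds ratios use the Haldane 0.5 correction when
any cell is zero. The 2×2 cells are fed to the test in a canonical order
so `test_edge(a, b)` and `test_edge(b, a)` return bit-identical floats.

Maximal cliques of the retained-edge graph come from networkx's
Bron–Kerbosch enumeration, filtered to size ≥ 3 ("more than two
interconnected nodes"); each clique carries its supporting enhancers (rows
where every member is present) and their deduplicated nearest target
genes. Hub motifs are a reporting flag (degree > 10), not a filter.

## RRHO

Ranking metric: `sign(log2FC) · (−log10 max(padj, 1e-300))`, ties broken by
descending log2FC then gene name — the convention of the RRHO literature
when a study combines effect direction with significance. The map evaluates,
for every rank-cutoff pair (s, t) on a step grid (default step `⌊N/100⌋`,
i.e. ≤ 100×100 cells), the exact hypergeometric upper tail of the overlap
between the two top lists, as −log10 p; a mirrored map over bottom ranks
captures co-downregulation. No correction over grid cells by default. The
most co-upregulated gene set is the top-s ∩ top-t at the maximising co-up
cell (ties: smallest s + t, then smallest s); both the argmax mode and a
fixed-cell mode are exposed because either convention appears in practice.

Hypergeometric tails are computed in-house in log space: lgamma for the
leading term plus a ratio-recurrence series summed until terms fall below
1e-17 of the running sum; below the distribution mode the complement is
summed instead and combined with `log1p(−exp(·))`. This keeps cells
accurate to ~1e-9 relative error in log space for overlaps whose p-values
underflow doubles (identity maps reach −log10 p ≈ 3000), and the
canonical (min, max) argument ordering makes `rrho_map(a,b)` exactly the
transpose of `rrho_map(b,a)`.

## Gene-set overlap and module scores

`hypergeometric_overlap` uses the same log-space tail; both p and −log10 p
are reported so overlaps at the 1e-76 scale are first-class. Sets are
intersected with the universe (with a warning) when they stray outside it.

`module_score` re-implements the standard single-cell signature score:
genes are binned into 24 bins by average expression (rank-based `qcut`, so
bins stay near-equal under ties), each signature gene draws 100 control
genes with replacement from its bin (signature genes excluded; empty bins
fall back to the nearest non-empty bin with a warning), and each cell's
score is mean signature expression minus mean pooled-control expression;
cluster scores are cell means. The 24/100 defaults are the published
defaults of the method this re-implements; the study this emulates states
neither. Known property: when a signature is shifted in only one cell
group, its average expression exceeds every null gene's, the signature
monopolises the top bin, and controls come from the next-highest nulls —
unshifted cells then score slightly negative (~−0.2 at 500 genes) while the
between-group contrast remains exact. The bundled expression generator
plants a balanced ±shift/2 so controls stay representative.

## Synthetic data: what it emulates and what it does not

The generator is the package's study-conditions definition, not a tuning
surface. Background sequence is order-0 i.i.d. with a single GC parameter
(matching GC-controlled random backgrounds; no higher-order Markov
structure, no repeats, no chromatin-state spatial structure). Motif
occurrences are sampled from the PWM (not fixed consensus) so scanner
thresholds are genuinely exercised; pairs/cliques are planted in a
without-replacement fraction of peaks at uniform non-overlapping offsets
and uniform strand, with a sizing error when a peak cannot hold its
plantings. Counts are negative binomial with `var = μ + α μ²`
(default mean 50–100, dispersion α = 0.03, typical of good bulk
ATAC/ChIP replicates; α < 1e-9 falls back to Poisson). DE tables put a
shared effect (default 2.0) plus independent N(0, 0.5) noise on a
controlled concordant fraction of true-DE genes, disjoint private up genes
for the remainder, z-implied p-values and BH padj. The three generators use
decoupled RNG streams (seed, seed+1, seed+2; helper tables seed+3/+4), and
equal seeds give byte-identical outputs.

Passing the recovery benchmarks therefore shows the machinery is correct
and calibrated under these idealized conditions; it does not show
robustness to real-data features the generator omits (repeat elements,
copy-number and mappability artifacts, correlated fragment counts,
overdispersed DE effect sizes, dropout).

## Problem sizes and determinism

The shipped experiments use 1,500–2,000 peaks of 200 bp, 10-motif
libraries, 4 vs 4 samples, and 4,000–10,000-gene universes — sizes at
which every benchmark (including 100-seed recovery sweeps) completes in
minutes on one CPU while leaving all statistics in their asymptotically
relevant regimes. All randomness flows from explicit seeds; pipeline runs
write a manifest (input checksums, seed, constants) and a `summary.json`
that is byte-identical across reruns with the same seed (images exempt).

## Defaults

| constant | default | meaning |
|---|---|---|
| `min_tag_count` | 4 | low-signal peak filter (max count across samples) |
| `fc_threshold` | 2 | fold-change cutoff for differential calls |
| `alpha` | 0.05 | BH-adjusted p cutoff |
| `edge_alpha` | 0.001 | raw Fisher p threshold for network edges |
| `min_clique_size` | 3 | cliques must have > 2 interconnected nodes |
| `hub_degree` | 10 | degree above which a node is flagged as a hub |
| PWM pseudocount | 0.01 | per cell, before log-odds |
| score threshold | 80% of max | when a library provides none |
| RRHO step | ⌊N/100⌋ | ≤ 100×100 grid |
| module-score bins / controls | 24 / 100 | published defaults of the scoring method |
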