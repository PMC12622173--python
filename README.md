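# regnet

Regulatory-network analysis of active enhancers for epigenomics studies of
myeloid / microglial cell identity — or any system where the question is
*which transcription factors act together on a set of regulatory elements,
and do two datasets agree about the downstream transcriptional program?*

The package implements, as a tested and fully synthetic-data-driven
pipeline:

1. **Differential peak analysis** — low-signal filtering (max tag count
   ≥ 4), median-column-sum depth normalization, and a simplified two-group
   test (pseudocounted log-ratio + Welch t on log2 counts + Benjamini–
   Hochberg), calling peaks at FC > 2 and padj < 0.05.
2. **Motif scanning and enrichment** — PWM log2-odds scanning on both
   strands, greedy resolution to non-overlapping high-confidence hits, and
   binomial enrichment of peak-level motif presence against a GC-matched
   random background:  p = P(X ≥ k_target), X ~ Binomial(n_target, f_bg).
3. **Motif co-occurrence networks** — for every motif pair on the active
   enhancers, a one-sided Fisher exact test of joint presence; edges kept at
   p < 0.001; **maximal cliques** (> 2 interconnected nodes, Bron–Kerbosch
   via networkx) with their supporting enhancers and nearest target genes;
   hub motifs flagged at degree > 10.
4. **RRHO concordance** — genes ranked by sign(log2FC)·(−log10 padj) in two
   differential-expression tables; a grid of exact hypergeometric overlap
   tests over rank-cutoff pairs gives a threshold-free concordance map and
   the most co-upregulated overlap gene set.
5. **Gene-set statistics** — exact log-space hypergeometric overlap tests
   (p-values like 1e-76 stay representable) and expression-bin-matched
   signature module scores aggregated over clusters.
6. **Synthetic data with ground truth** — GC-controlled random enhancers
   with planted motif pairs/cliques, negative-binomial count tables with
   planted fold changes, and paired DE tables with a controlled concordant
   fraction, so every stage is benchmarked against known truth.

## Worked example

The numbered scripts under `analysis/` run the demo study (1,500 synthetic
enhancers, a planted IRF–FLI–MEF–MAF-style 4-motif clique on 40% of peaks,
two-sided planted fold changes on 200 peaks, and a 4,000-gene DE pair
sharing 200 concordantly up genes):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_differential_peaks.py
python analysis/03_motif_enrichment.py
python analysis/04_cooccurrence_network.py
python analysis/05_rrho_concordance.py
python analysis/06_geneset_scores.py
```

Output of the network stage (seed 1):

```
7 motifs with presence on 87 enhancers
6 significant edges (p < 0.001); hubs (degree > 10): none
clique M_FLI-M_IRF-M_MAF-M_MEF: 15 supporting enhancers, 14 target genes
```

All six pairwise edges among the four planted motifs are significant, they
form the single maximal clique, and its supporting enhancers map to their
nearest genes. The RRHO stage reports:

```
RRHO over 4000 genes (step 40); map max -log10 p = 89.9
174 co-upregulated genes at rank cutoffs (s=360, t=400), cell -log10 p = 89.9
Jaccard with the planted concordant-up set: 0.84
```

i.e. the overlap gene set read off at the map's maximising cell recovers
the planted concordant genes. The gene-set stage prints the exact
hypergeometric overlap of the two tables' up genes (p = 1.3e-89 here) and
cluster module scores of ±1.01 for the planted ±1-shift signature.

The same pipeline is available as a CLI (`regnet run-all --seed 1
--out-dir run/`, plus per-stage subcommands `simulate`, `diff`, `scan`,
`enrich`, `network`, `cliques`, `rrho`, `score`, `overlap`), writing a
manifest with input checksums and a machine-readable `summary.json`.

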