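"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the data the pipeline consumes in real studies without any
sequencing data: (a) enhancer peak sequences on a GC-controlled i.i.d.
random contig with motif occurrences planted at known offsets, including
pairwise and clique-level co-occurrence at controlled fractions of peaks;
(b) two-condition negative-binomial tag-count tables with planted log2 fold
changes; (c) paired differential-expression tables with a controlled
fraction of concordantly upregulated genes. Every generator is a pure
function of the seed: equal seeds give byte-identical outputs. The three
generators use decoupled RNG streams seeded seed, seed+1, seed+2 (helper
tables use seed+3, seed+4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .intervals import PeakSet, TssAnnotation, write_bed, write_tss_tsv
from .motifs import BASES, Pwm, reverse_complement, write_fasta, write_homer_motifs

PEAK_GAP_BP = 200  # spacing between synthetic peaks on the contig
CONTIG = "chrS"


class SizingError(ValueError):
    """Peak too short to hold the required non-overlapping plantings."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic inputs.

    Fractions are of the peak (or gene) universe; planted_pairs entries are
    (motif_a, motif_b, co_occurrence_fraction) and planted_cliques entries
    (motif_id tuple, fraction) — a single-member tuple plants background
    presence for one motif. nb_dispersion is the NB over-dispersion alpha in
    var = mu + alpha mu^2 (alpha -> 0 recovers Poisson).
    """

    seed: int = 0
    n_peaks: int = 1000
    peak_length_bp: int = 200
    gc_fraction: float = 0.5
    pwm_library: list[Pwm] = field(default_factory=list)
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    planted_cliques: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    n_samples_per_condition: int = 4
    nb_mean: float = 50.0
    nb_dispersion: float = 0.03
    planted_fc_peaks: list[tuple[int, float]] = field(default_factory=list)
    de_n_genes: int = 10000
    de_shared_fraction: float = 0.5
    de_true_fraction: float = 0.05
    de_effect: float = 2.0
    de_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        for frac in (self.de_shared_fraction, self.de_true_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        for *_, frac in self.planted_pairs:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("planted pair fractions must be in [0, 1]")
        for _, frac in self.planted_cliques:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("planted clique fractions must be in [0, 1]")
        if self.nb_mean <= 0 or self.nb_dispersion < 0:
            raise ValueError("nb_mean must be positive and nb_dispersion >= 0")
        if self.pwm_library:
            longest = max(p.length for p in self.pwm_library)
            if self.peak_length_bp < longest:
                raise SizingError(
                    f"peak_length_bp {self.peak_length_bp} shorter than the "
                    f"longest motif ({longest} bp)"
                )
        known = {p.motif_id for p in self.pwm_library}
        referenced = {m for a, b, _ in self.planted_pairs for m in (a, b)}
        referenced |= {m for members, _ in self.planted_cliques for m in members}
        unknown = referenced - known
        if unknown:
            raise ValueError(f"planted motifs absent from library: {sorted(unknown)}")

    @property
    def pwms_by_id(self) -> dict[str, Pwm]:
        return {p.motif_id: p for p in self.pwm_library}


@dataclass
class SyntheticTruth:
    """Ground truth of what was planted, for recovery tests."""

    planted_hits: list[tuple[str, str, int, str]] = field(default_factory=list)
    planted_clique_peaks: dict[str, list[str]] = field(default_factory=dict)
    true_log2fc: dict[str, float] = field(default_factory=dict)
    true_de_status: dict[str, dict[str, str]] = field(default_factory=dict)
    shared_up_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["planted_hits"] = [tuple(h) for h in d.get("planted_hits", [])]
        return cls(**d)


def _peak_id(i: int) -> str:
    return f"peak_{i:05d}"


def generate_peak_sequences(
    config: SimulationConfig,
) -> tuple[PeakSet, dict[str, str], SyntheticTruth]:
    """Random GC-controlled peak sequences with planted motif occurrences.

    Bases are i.i.d. with P(G) + P(C) = gc_fraction. For each planted pair or
    clique, the stated fraction of peaks (drawn without replacement) receives
    one occurrence of every member motif, sampled from the PWM's
    per-position distributions, on a uniform strand at a uniform offset among
    those that do not overlap previously planted occurrences in the peak.
    """
    rng = np.random.default_rng(config.seed)
    n, L = config.n_peaks, config.peak_length_bp
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_idx = rng.choice(4, size=(n, L), p=probs)
    seqs = [[BASES[j] for j in row] for row in base_idx]
    occupied: dict[int, list[tuple[int, int]]] = {}
    truth = SyntheticTruth()
    pwms = config.pwms_by_id
    groups: list[tuple[tuple[str, ...], float]] = [
        ((a, b), f) for a, b, f in config.planted_pairs
    ] + [(tuple(members), f) for members, f in config.planted_cliques]
    for members, frac in groups:
        n_sel = int(round(frac * n))
        selected = rng.choice(n, size=n_sel, replace=False)
        key = ";".join(members)
        truth.planted_clique_peaks[key] = [_peak_id(int(i)) for i in sorted(selected)]
        for i in selected:
            spans = occupied.setdefault(int(i), [])
            for motif_id in members:
                pwm = pwms[motif_id]
                instance = pwm.sample(rng)
                strand = "+" if rng.random() < 0.5 else "-"
                allowed = [
                    off
                    for off in range(L - pwm.length + 1)
                    if all(off + pwm.length <= s or off >= e for s, e in spans)
                ]
                if not allowed:
                    raise SizingError(
                        f"peak {_peak_id(int(i))} ({L} bp) cannot hold another "
                        f"non-overlapping {pwm.length} bp occurrence of {motif_id}"
                    )
                off = int(allowed[rng.integers(0, len(allowed))])
                written = instance if strand == "+" else reverse_complement(instance)
                seqs[i][off : off + pwm.length] = list(written)
                spans.append((off, off + pwm.length))
                truth.planted_hits.append((_peak_id(int(i)), motif_id, off, strand))
    sequences = {_peak_id(i): "".join(s) for i, s in enumerate(seqs)}
    starts = np.arange(n) * (L + PEAK_GAP_BP)
    intervals = pd.DataFrame(
        {
            "chrom": CONTIG,
            "start": starts,
            "end": starts + L,
            "strand": ".",
        },
        index=pd.Index([_peak_id(i) for i in range(n)], name="peak_id"),
    )
    return PeakSet(intervals), sequences, truth


def generate_count_table(
    config: SimulationConfig, peaks: PeakSet, truth: SyntheticTruth | None = None
) -> pd.DataFrame:
    """Two-condition negative-binomial tag counts over the peaks.

    Condition A has mean nb_mean everywhere; condition B multiplies the mean
    by 2^log2FC at the planted peaks. var = mu + nb_dispersion * mu^2; a
    dispersion below 1e-9 falls back to Poisson.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(peaks)
    for idx, _ in config.planted_fc_peaks:
        if not 0 <= idx < n:
            raise ValueError(f"planted_fc_peaks index {idx} out of range")
    mu_a = np.full(n, config.nb_mean)
    mu_b = mu_a.copy()
    for idx, lfc in config.planted_fc_peaks:
        mu_b[idx] = config.nb_mean * 2.0**lfc
        if truth is not None:
            truth.true_log2fc[peaks.peak_ids[idx]] = float(lfc)
    k = config.n_samples_per_condition
    cols = [f"A_{j + 1}" for j in range(k)] + [f"B_{j + 1}" for j in range(k)]
    data = np.empty((n, 2 * k), dtype=np.int64)
    disp = config.nb_dispersion
    for j in range(k):
        data[:, j] = _nb_draw(rng, mu_a, disp)
    for j in range(k):
        data[:, k + j] = _nb_draw(rng, mu_b, disp)
    return pd.DataFrame(data, index=pd.Index(peaks.peak_ids, name="peak_id"), columns=cols)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-9:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_paired_de_tables(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Two differential-expression tables over one gene universe.

    A de_true_fraction of genes is truly DE; of those, de_shared_fraction
    are concordantly up in both tables (shared effect de_effect plus
    independent N(0, de_noise_sd) noise), the rest are up in one table only
    (disjoint private sets); all other genes are null. p-values come from
    the implied z-scores with de_noise_sd as the standard error; padj is BH.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.de_n_genes
    genes = [f"gene_{i:05d}" for i in range(n)]
    n_true = int(round(config.de_true_fraction * n))
    n_shared = int(round(config.de_shared_fraction * n_true))
    n_private = n_true - n_shared
    perm = rng.permutation(n)
    shared = [genes[i] for i in perm[:n_shared]]
    private_a = [genes[i] for i in perm[n_shared : n_shared + n_private]]
    private_b = [genes[i] for i in perm[n_shared + n_private : n_shared + 2 * n_private]]
    truth = SyntheticTruth(shared_up_genes=sorted(shared))

    def one_table(up_genes: set[str]) -> pd.DataFrame:
        lfc = rng.normal(0.0, config.de_noise_sd, size=n)
        up_mask = np.array([g in up_genes for g in genes])
        lfc[up_mask] += config.de_effect
        se = max(config.de_noise_sd, 1e-12)
        z = lfc / se
        pvalue = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
        padj = multipletests(pvalue, method="fdr_bh")[1]
        return pd.DataFrame(
            {"log2fc": lfc, "pvalue": pvalue, "padj": padj},
            index=pd.Index(genes, name="gene"),
        )

    up_a = set(shared) | set(private_a)
    up_b = set(shared) | set(private_b)
    table_a = one_table(up_a)
    table_b = one_table(up_b)
    truth.true_de_status = {
        "a": {g: ("up" if g in up_a else "null") for g in genes},
        "b": {g: ("up" if g in up_b else "null") for g in genes},
    }
    return table_a, table_b, truth


def generate_tss_table(
    config: SimulationConfig, peaks: PeakSet, max_offset_bp: int = 2000
) -> TssAnnotation:
    """One gene TSS per peak, at a uniform offset within +/- max_offset_bp of
    the peak midpoint, so nearest-gene annotation has a known answer."""
    rng = np.random.default_rng(config.seed + 3)
    rows = []
    for i, (peak_id, row) in enumerate(peaks.intervals.iterrows()):
        center = (int(row["start"]) + int(row["end"])) // 2
        offset = int(rng.integers(-max_offset_bp, max_offset_bp + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"GENE_{i:05d}", row["chrom"], max(0, center + offset), strand))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"]).set_index("gene")
    return TssAnnotation(df)


def generate_expression(
    config: SimulationConfig,
    n_cells: int = 200,
    n_genes: int = 300,
    n_signature: int = 20,
    shift: float = 2.0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Small cells x genes matrix with a signature shifted in one cluster.

    The shift is balanced (+shift/2 in cluster "c1", -shift/2 in "c0") so
    the signature's average expression matches the null genes' and
    bin-matched controls stay representative; the between-cluster score
    contrast is `shift`. Returns (expression, cluster labels, signature).
    """
    rng = np.random.default_rng(config.seed + 4)
    genes = [f"sc_gene_{i:04d}" for i in range(n_genes)]
    cells = [f"cell_{i:04d}" for i in range(n_cells)]
    expr = rng.normal(0.0, 1.0, size=(n_cells, n_genes))
    signature = genes[:n_signature]
    half = n_cells // 2
    expr[half:, :n_signature] += shift / 2
    expr[:half, :n_signature] -= shift / 2
    clusters = pd.Series(
        ["c0"] * half + ["c1"] * (n_cells - half), index=cells, name="cluster"
    )
    return pd.DataFrame(expr, index=cells, columns=genes), clusters, signature


def write_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the full input bundle the pipeline subcommands read.

    FASTA peak sequences, BED6 peak coordinates, TSV tag counts and sample
    group map, TSV DE tables, TSS table, HOMER-format motif library,
    expression matrix + cluster labels + signature gene set, and the JSON
    ground-truth record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peaks, sequences, truth = generate_peak_sequences(config)
    counts = generate_count_table(config, peaks, truth)
    de_a, de_b, de_truth = generate_paired_de_tables(config)
    truth.true_de_status = de_truth.true_de_status
    truth.shared_up_genes = de_truth.shared_up_genes
    tss = generate_tss_table(config, peaks)
    expr, clusters, signature = generate_expression(config)
    paths = {
        "fasta": out / "peaks.fa",
        "bed": out / "peaks.bed",
        "counts": out / "counts.tsv",
        "groups": out / "groups.tsv",
        "motifs": out / "library.motif",
        "tss": out / "tss.tsv",
        "de_a": out / "de_a.tsv",
        "de_b": out / "de_b.tsv",
        "expression": out / "expression.tsv",
        "clusters": out / "clusters.tsv",
        "signature": out / "signature.txt",
        "truth": out / "truth.json",
    }
    write_fasta(sequences, paths["fasta"])
    write_bed(peaks, paths["bed"])
    counts.to_csv(paths["counts"], sep="\t")
    with open(paths["groups"], "w") as fh:
        for s in counts.columns:
            fh.write(f"{s}\t{'A' if s.startswith('A') else 'B'}\n")
    write_homer_motifs(config.pwm_library, paths["motifs"])
    write_tss_tsv(tss, paths["tss"])
    de_a.to_csv(paths["de_a"], sep="\t")
    de_b.to_csv(paths["de_b"], sep="\t")
    expr.round(6).to_csv(paths["expression"], sep="\t")
    clusters.rename_axis("cell").to_frame().to_csv(paths["clusters"], sep="\t")
    with open(paths["signature"], "w") as fh:
        fh.write("\n".join(signature) + "\n")
    truth.to_json(paths["truth"])
    return paths
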