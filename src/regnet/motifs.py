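"""Position weight matrices: log-odds scanning, non-overlapping hit
resolution, GC-matched background sequences and binomial motif enrichment.

Scores are log2-odds ("bits"): sum over positions of log2(p_motif /
p_background). Matrices carry a per-cell pseudocount of 0.01 so no cell is
zero and scores stay finite. Enrichment follows the known-motif convention
of peak-level presence fractions tested against a binomial upper tail on a
GC-matched background set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import log_binom_sf, neg_log10_from_ln

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PWM_PSEUDOCOUNT = 0.01
DEFAULT_THRESHOLD_FRACTION = 0.8  # of the maximum attainable log2-odds score
UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass
class Pwm:
    """A position probability matrix with a scanning threshold in bits."""

    motif_id: str
    matrix: np.ndarray  # (L, 4) rows over A,C,G,T, each summing to 1
    score_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be (L, 4)")
        if (self.matrix <= 0).any():
            raise ValueError(f"{self.motif_id}: zero cells; apply a pseudocount")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: rows must sum to 1")
        if self.score_threshold > self.max_score() + 1e-9:
            raise ValueError(f"{self.motif_id}: threshold exceeds maximum score")

    @classmethod
    def from_probabilities(
        cls,
        motif_id: str,
        rows: Sequence[Sequence[float]],
        score_threshold: float | None = None,
        pseudocount: float = PWM_PSEUDOCOUNT,
    ) -> "Pwm":
        m = np.asarray(rows, dtype=float)
        m = m + pseudocount
        m = m / m.sum(axis=1, keepdims=True)
        pwm = cls(motif_id, m, score_threshold=-math.inf)
        pwm.score_threshold = (
            pwm.default_threshold() if score_threshold is None else float(score_threshold)
        )
        return pwm

    @classmethod
    def from_consensus(
        cls,
        motif_id: str,
        consensus: str,
        p_consensus: float = 0.97,
        score_threshold: float | None = None,
    ) -> "Pwm":
        """Sharp PWM putting p_consensus (pre-pseudocount mass) on each
        consensus base; handy for simulations and tests."""
        rows = []
        off = (1.0 - p_consensus) / 3.0
        for base in consensus.upper():
            row = [off] * 4
            row[_BASE_INDEX[base]] = p_consensus
            rows.append(row)
        return cls.from_probabilities(motif_id, rows, score_threshold=score_threshold)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
        return np.log2(self.matrix / bg)

    def max_score(self, background: np.ndarray | None = None) -> float:
        return float(self.log_odds(background).max(axis=1).sum())

    def default_threshold(self, fraction: float = DEFAULT_THRESHOLD_FRACTION) -> float:
        """Threshold as a fraction of the maximum log2-odds score under a
        uniform background; used when a motif library carries none."""
        return fraction * self.max_score()

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one occurrence from the per-position base distributions."""
        draws = [rng.choice(4, p=row) for row in self.matrix]
        return "".join(BASES[i] for i in draws)


@dataclass(frozen=True)
class MotifHit:
    """A scored motif match inside one peak sequence (0-based offset)."""

    peak_id: str
    motif_id: str
    offset: int
    strand: str
    score: float
    length: int

    @property
    def span(self) -> tuple[int, int]:
        return self.offset, self.offset + self.length


def scan_sequence(
    seq: str,
    pwm: Pwm,
    background: np.ndarray | None = None,
    peak_id: str = "",
) -> list[MotifHit]:
    """All windows on both strands scoring at or above the PWM threshold.

    Windows containing N are skipped. Reverse-strand hits are reported in
    forward coordinates: offset' = len(seq) - L - offset_on_rc.
    """
    L = pwm.length
    n = len(seq)
    if n < L:
        return []
    lo = pwm.log_odds(background)
    hits: list[MotifHit] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        enc = encode_sequence(s)
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        valid = (windows < 4).all(axis=1)
        # gather per-position log-odds for every window; N-windows masked out
        safe = np.where(windows < 4, windows, 0)
        scores = lo[np.arange(L)[None, :], safe].sum(axis=1)
        scores[~valid] = -np.inf
        for off in np.flatnonzero(scores >= pwm.score_threshold):
            fwd = int(off) if strand == "+" else n - L - int(off)
            hits.append(
                MotifHit(peak_id, pwm.motif_id, fwd, strand, float(scores[off]), L)
            )
    return hits


def resolve_nonoverlapping(hits: Iterable[MotifHit]) -> list[MotifHit]:
    """Greedy non-overlapping hit selection within one peak.

    Hits are taken in descending score order (ties: leftmost offset, then +
    strand, then motif id); a hit is kept iff its span overlaps no kept span,
    regardless of motif identity.
    """
    ordered = sorted(
        hits,
        key=lambda h: (-h.score, h.offset, 0 if h.strand == "+" else 1, h.motif_id),
    )
    kept: list[MotifHit] = []
    spans: list[tuple[int, int]] = []
    for h in ordered:
        s, e = h.span
        if all(e <= ks or s >= ke for ks, ke in spans):
            kept.append(h)
            spans.append((s, e))
    return sorted(kept, key=lambda h: (h.offset, h.motif_id))


def _scan_batch(
    sequences: Mapping[str, str],
    pwms: Sequence[Pwm],
    background: np.ndarray | None,
) -> dict[str, list[MotifHit]]:
    """Vectorized scan of equal-length sequences: one gather per PWM/strand
    over the stacked (n_peaks, length) base matrix."""
    ids = list(sequences)
    n = len(ids)
    length = len(next(iter(sequences.values())))
    enc_fwd = np.empty((n, length), dtype=np.int8)
    enc_rev = np.empty((n, length), dtype=np.int8)
    for i, pid in enumerate(ids):
        enc_fwd[i] = encode_sequence(sequences[pid])
        enc_rev[i] = encode_sequence(reverse_complement(sequences[pid]))
    out: dict[str, list[MotifHit]] = {pid: [] for pid in ids}
    for pwm in pwms:
        L = pwm.length
        if length < L:
            continue
        lo = pwm.log_odds(background)
        for strand, enc in (("+", enc_fwd), ("-", enc_rev)):
            windows = np.lib.stride_tricks.sliding_window_view(enc, L, axis=1)
            safe = np.where(windows < 4, windows, 0)
            scores = lo[np.arange(L)[None, None, :], safe].sum(axis=2)
            scores[~(windows < 4).all(axis=2)] = -np.inf
            for i, off in zip(*np.nonzero(scores >= pwm.score_threshold)):
                fwd = int(off) if strand == "+" else length - L - int(off)
                out[ids[i]].append(
                    MotifHit(ids[i], pwm.motif_id, fwd, strand,
                             float(scores[i, off]), L)
                )
    return out


def scan_peaks(
    sequences: Mapping[str, str],
    pwms: Sequence[Pwm],
    background: np.ndarray | None = None,
    resolve: bool = True,
) -> pd.DataFrame:
    """Scan every peak with every PWM; optionally resolve overlaps per peak.

    Returns a tidy table (peak_id, motif_id, offset, strand, score, length).
    Equal-length peak sets take a batched vectorized path; the result is
    identical to per-sequence scanning.
    """
    lengths = {len(s) for s in sequences.values()}
    rows: list[MotifHit] = []
    if len(lengths) == 1 and len(sequences) > 1:
        by_peak = _scan_batch(sequences, pwms, background)
        for peak_id in sequences:
            peak_hits = by_peak[peak_id]
            if resolve:
                peak_hits = resolve_nonoverlapping(peak_hits)
            rows.extend(peak_hits)
    else:
        for peak_id, seq in sequences.items():
            peak_hits = []
            for pwm in pwms:
                peak_hits.extend(scan_sequence(seq, pwm, background, peak_id=peak_id))
            if resolve:
                peak_hits = resolve_nonoverlapping(peak_hits)
            rows.extend(peak_hits)
    return pd.DataFrame(
        [(h.peak_id, h.motif_id, h.offset, h.strand, h.score, h.length) for h in rows],
        columns=["peak_id", "motif_id", "offset", "strand", "score", "length"],
    )


def generate_gc_background(
    sequences: Mapping[str, str],
    n_background: int | None = None,
    seed: int = 0,
    gc_bin_width: float = 0.02,
) -> dict[str, str]:
    """Random sequences matched to the targets' GC and length distributions.

    Targets are cycled round-robin so every target contributes its GC
    (binned to gc_bin_width) and length proportionally to bin occupancy;
    with n_background equal to the target count the length multiset is
    reproduced exactly. Default n_background is twice the target count.
    """
    targets = list(sequences.items())
    if not targets:
        raise ValueError("no target sequences")
    if n_background is None:
        n_background = 2 * len(targets)
    if n_background < len(targets):
        raise ValueError("n_background must be at least the number of targets")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for i in range(n_background):
        _, seq = targets[i % len(targets)]
        gc = gc_fraction(seq)
        # snap to the centre of the 2%-wide GC bin
        gc = min(1.0, (math.floor(gc / gc_bin_width) + 0.5) * gc_bin_width)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        draw = rng.choice(4, size=len(seq), p=p)
        out[f"bg_{i:06d}"] = "".join(BASES[j] for j in draw)
    return out


def motif_enrichment(
    target_hits: pd.DataFrame,
    background_hits: pd.DataFrame,
    n_target_peaks: int,
    n_background_peaks: int,
    motif_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binomial enrichment of peak-level motif presence against background.

    For each motif, k_target = number of target peaks with >= 1 resolved hit;
    the background fraction (floored at 0.5 / n_background_peaks) parameterises
    a Binomial(n_target_peaks, bg_fraction) upper tail p = P(X >= k_target).
    Rows sorted by ascending p. log_p is natural log; neg_log10_p is the
    display scale.
    """
    if n_background_peaks <= 0:
        raise ValueError("need a non-empty background peak set")
    if motif_ids is None:
        motif_ids = sorted(
            set(target_hits.get("motif_id", pd.Series(dtype=str)))
            | set(background_hits.get("motif_id", pd.Series(dtype=str)))
        )
    tcounts = (
        target_hits.groupby("motif_id")["peak_id"].nunique()
        if len(target_hits)
        else pd.Series(dtype=int)
    )
    bcounts = (
        background_hits.groupby("motif_id")["peak_id"].nunique()
        if len(background_hits)
        else pd.Series(dtype=int)
    )
    rows = []
    for motif in motif_ids:
        k_t = int(tcounts.get(motif, 0))
        k_b = int(bcounts.get(motif, 0))
        bg_frac = max(k_b, 0.5) / n_background_peaks
        bg_frac = min(bg_frac, 1.0)
        log_p = log_binom_sf(k_t, n_target_peaks, bg_frac)
        rows.append(
            {
                "motif_id": motif,
                "k_target": k_t,
                "target_fraction": k_t / n_target_peaks,
                "target_percent": 100.0 * k_t / n_target_peaks,
                "k_background": k_b,
                "background_fraction": bg_frac,
                "log_p": log_p,
                "neg_log10_p": neg_log10_from_ln(log_p),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["log_p", "motif_id"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# motif file formats


def read_homer_motifs(path: str | Path) -> list[Pwm]:
    """HOMER .motif text: '>consensus<TAB>name<TAB>threshold' then one
    probability row (A C G T) per position. Thresholds, when present, are
    used as-is on the scanner's bits scale; otherwise the default
    80%-of-maximum threshold is assigned."""
    pwms: list[Pwm] = []
    header: list[str] | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        name = header[1] if len(header) > 1 else header[0].lstrip(">")
        thr = float(header[2]) if len(header) > 2 else None
        # files with strictly positive cells are taken as already
        # pseudocounted; only zero-containing matrices get the 0.01
        pc = 0.0 if min(min(r) for r in rows) > 0 else PWM_PSEUDOCOUNT
        pwms.append(Pwm.from_probabilities(name, rows, score_threshold=thr, pseudocount=pc))
        header, rows = None, []

    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            header = line.rstrip().split("\t")
        else:
            rows.append([float(x) for x in line.split()])
    flush()
    if not pwms:
        raise ValueError(f"{path}: no motifs found")
    return pwms


def write_homer_motifs(pwms: Sequence[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.consensus}\t{pwm.motif_id}\t{pwm.score_threshold:.6f}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def read_jaspar_motifs(path: str | Path) -> list[Pwm]:
    """JASPAR PFM files via Bio.motifs; counts are normalized to
    probabilities and given the standard pseudocount."""
    from Bio import motifs as bio_motifs

    pwms: list[Pwm] = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float).T
            probs = counts / counts.sum(axis=1, keepdims=True)
            name = m.matrix_id or m.name
            pwms.append(Pwm.from_probabilities(str(name), probs))
    if not pwms:
        raise ValueError(f"{path}: no motifs found")
    return pwms


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
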