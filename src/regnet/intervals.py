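"""Genomic intervals, peak sets, replicate selection and TSS annotation.

Coordinates are 0-based half-open throughout (BED convention). Peak
"position" for TSS distance is the integer midpoint floor((start+end)/2).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROXIMAL_MAX_BP = 500  # |distance| < 500 -> proximal
DISTAL_MIN_BP = 1000  # |distance| > 1000 -> distal; the 500-1000 band is "intermediate"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class PeakSet:
    """Ordered peaks with optional per-sample tag counts.

    intervals: DataFrame indexed by unique peak_id with columns
        chrom, start, end, strand.
    counts: optional DataFrame (same index) with one column per sample.
    """

    intervals: pd.DataFrame
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        missing = required - set(self.intervals.columns)
        if missing:
            raise ValueError(f"intervals missing columns: {sorted(missing)}")
        if "strand" not in self.intervals.columns:
            self.intervals = self.intervals.assign(strand=".")
        if self.intervals.index.has_duplicates:
            dupes = self.intervals.index[self.intervals.index.duplicated()].unique()
            raise ValueError(f"duplicate peak ids: {list(dupes)[:5]}")
        bad = self.intervals.query("start < 0 or start >= end")
        if len(bad):
            raise ValueError(f"malformed intervals for peaks {list(bad.index)[:5]}")
        if self.counts is not None:
            if not self.counts.index.equals(self.intervals.index):
                self.counts = self.counts.reindex(self.intervals.index)
                if self.counts.isna().any().any():
                    raise ValueError("count matrix rows do not match peak ids")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.intervals.index)

    @property
    def samples(self) -> list[str]:
        return [] if self.counts is None else list(self.counts.columns)

    def subset(self, peak_ids: Sequence[str]) -> "PeakSet":
        counts = None if self.counts is None else self.counts.loc[list(peak_ids)]
        return PeakSet(self.intervals.loc[list(peak_ids)].copy(), counts)


@dataclass
class TssAnnotation:
    """One primary TSS per gene symbol: DataFrame gene -> chrom, tss, strand."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"chrom", "tss", "strand"} - set(self.table.columns)
        if missing:
            raise ValueError(f"TSS table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("multiple TSS rows for one gene symbol")

    def __len__(self) -> int:
        return len(self.table)


def merge_peaks(peak_sets: Iterable[PeakSet]) -> PeakSet:
    """Merge overlapping intervals across peak sets into bounding intervals.

    Any two intervals on the same chromosome sharing >= 1 bp are merged,
    transitively; half-open abutting intervals are not merged. Output is
    ordered by (chrom, start) with fresh ids ``merged_<k>``. Tag counts are
    dropped: merged peaks must be re-annotated against the samples.
    """
    peak_sets = list(peak_sets)
    if not peak_sets:
        raise ValueError("need at least one peak set")
    frames = [ps.intervals[["chrom", "start", "end"]] for ps in peak_sets]
    allp = pd.concat(frames, ignore_index=True).sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    )
    merged: list[tuple[str, int, int]] = []
    cur: tuple[str, int, int] | None = None
    for chrom, start, end in allp.itertuples(index=False):
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur = (cur[0], cur[1], max(cur[2], end))
        else:
            if cur is not None:
                merged.append(cur)
            cur = (chrom, int(start), int(end))
    if cur is not None:
        merged.append(cur)
    out = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    out["strand"] = "."
    out.index = [f"merged_{k}" for k in range(len(out))]
    return PeakSet(out)


def select_best_replicate_pair(peak_set: PeakSet) -> tuple[str, str, float]:
    """Pick the two samples whose log2(count+1) profiles correlate best.

    Pearson correlation across peaks; ties broken by lexicographic sample
    pair; a constant count vector makes the correlation undefined and scores
    the pair as -inf with a warning.
    """
    if peak_set.counts is None or len(peak_set.samples) < 2:
        raise ValueError("need a count matrix with at least two samples")
    if len(peak_set) < 2:
        raise ValueError("need at least two peaks to correlate replicates")
    logc = np.log2(peak_set.counts.to_numpy(dtype=float) + 1.0)
    samples = peak_set.samples
    best: tuple[str, str] | None = None
    best_r = -math.inf
    for ia, ib in combinations(range(len(samples)), 2):
        a, b = sorted((samples[ia], samples[ib]))
        va, vb = logc[:, ia], logc[:, ib]
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            warnings.warn(
                f"constant counts for pair ({a}, {b}); correlation undefined",
                stacklevel=2,
            )
            r = -math.inf
        else:
            r = float(np.corrcoef(va, vb)[0, 1])
        if r > best_r or (r == best_r and best is not None and (a, b) < best):
            best, best_r = (a, b), r
    assert best is not None
    return best[0], best[1], best_r


def annotate_peaks_to_genes(peaks: PeakSet, tss: TssAnnotation) -> pd.DataFrame:
    """Assign each peak to its nearest TSS and classify by distance.

    Distance is from the peak midpoint to the TSS in bp; the sign is positive
    when the midpoint lies downstream of the TSS on the gene's strand.
    Classes: proximal (|d| < 500), distal (|d| > 1000), intermediate
    otherwise. Nearest gene by minimal |d|, ties alphabetical. Peaks on a
    chromosome with no TSS get nearest_gene=None and class distal, with a
    warning.
    """
    if len(tss) == 0:
        raise ValueError("empty TSS annotation")
    records = []
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values(["tss", "strand"]).sort_values("tss", kind="mergesort")
        for c, g in tss.table.groupby("chrom")
    }
    prepared = {}
    for chrom, g in by_chrom.items():
        pos = g["tss"].to_numpy(dtype=np.int64)
        prepared[chrom] = (pos, g)
    missing_chroms: set[str] = set()
    for peak_id, row in peaks.intervals.iterrows():
        chrom = str(row["chrom"])
        center = (int(row["start"]) + int(row["end"])) // 2
        if chrom not in prepared:
            missing_chroms.add(chrom)
            records.append((peak_id, None, np.nan, "distal"))
            continue
        pos, g = prepared[chrom]
        j = int(np.searchsorted(pos, center))
        cand: list[int] = []
        if j < len(pos):
            cand.append(j)
        if j > 0:
            cand.append(j - 1)
        dmin = min(abs(center - int(pos[c])) for c in cand)
        # gather every TSS at exactly dmin on either side (duplicated
        # positions sit in contiguous runs of the sorted array)
        hits: list[tuple[str, int]] = []
        for target in {center - dmin, center + dmin}:
            left = int(np.searchsorted(pos, target, side="left"))
            right = int(np.searchsorted(pos, target, side="right"))
            for idx in range(left, right):
                gene = g.index[idx]
                hits.append((str(gene), int(pos[idx])))
        gene, tss_pos = min(hits)
        strand = str(g.loc[gene, "strand"])
        signed = center - tss_pos if strand != "-" else tss_pos - center
        ad = abs(signed)
        if ad < PROXIMAL_MAX_BP:
            cls = "proximal"
        elif ad > DISTAL_MIN_BP:
            cls = "distal"
        else:
            cls = "intermediate"
        records.append((peak_id, gene, signed, cls))
    if missing_chroms:
        warnings.warn(
            f"no TSS on chromosome(s) {sorted(missing_chroms)}; peaks classed distal",
            stacklevel=2,
        )
    out = pd.DataFrame(
        records, columns=["peak_id", "nearest_gene", "distance", "tss_class"]
    ).set_index("peak_id")
    return out


# ---------------------------------------------------------------------------
# file formats


def read_bed(path: str | Path) -> PeakSet:
    """Read a BED6 (or BED3/4) file into a PeakSet."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: fewer than 3 BED fields")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 else f"peak_{ln}"
        strand = parts[5] if len(parts) > 5 and parts[5] in "+-." else "."
        rows.append((name, chrom, start, end, strand))
    df = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end", "strand"])
    return PeakSet(df.set_index("peak_id"))


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for peak_id, row in peaks.intervals.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{peak_id}\t0\t{row['strand']}\n"
            )


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Tag-count TSV: first column peak_id, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no sample columns")
    return df


def read_tss_tsv(path: str | Path) -> TssAnnotation:
    """TSS TSV with columns gene, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "chrom", "tss", "strand"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return TssAnnotation(df.set_index("gene"))


def write_tss_tsv(tss: TssAnnotation, path: str | Path) -> None:
    tss.table.rename_axis("gene").reset_index().to_csv(path, sep="\t", index=False)
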