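"""Rank-rank hypergeometric overlap (RRHO) between two differential
expression tables sharing a gene universe.

Genes are ranked by a signed significance metric, sign(log2FC) x
(-log10 padj), from most significantly up (rank 1) to most significantly
down (rank N). For every pair of rank cutoffs (s, t) on a step grid, the
overlap of the two top lists is scored with a hypergeometric upper tail,
giving a threshold-free concordance map; the mirrored map over bottom ranks
captures co-downregulation. The most co-upregulated overlap gene set is read
off at the map's maximising cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import log_hypergeom_sf, neg_log10_from_ln

PADJ_FLOOR = 1e-300


def compute_ranking(table: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by signed significance.

    table: indexed by gene with columns log2fc and padj (missing padj
    treated as 1). Adds ranking_metric = sign(log2fc) * (-log10 max(padj,
    1e-300)) and rank (1 = most significantly up; ties broken by descending
    log2fc then gene name).
    """
    if table.index.has_duplicates:
        dupes = sorted(table.index[table.index.duplicated()].unique())
        raise ValueError(f"duplicate gene symbols: {dupes[:10]}")
    out = table.copy()
    if not np.isfinite(out["log2fc"]).all():
        raise ValueError("non-finite log2fc values")
    padj = out["padj"].fillna(1.0) if "padj" in out.columns else pd.Series(1.0, index=out.index)
    metric = np.sign(out["log2fc"].to_numpy()) * (
        -np.log10(np.maximum(padj.to_numpy(dtype=float), PADJ_FLOOR))
    )
    out["ranking_metric"] = metric
    order = out.assign(_gene=out.index.astype(str)).sort_values(
        ["ranking_metric", "log2fc", "_gene"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    out["rank"] = ranks.reindex(out.index)
    return out


@dataclass
class RrhoMap:
    """Grid of hypergeometric overlap scores over rank-cutoff pairs.

    neglog10[i, j] scores the overlap of list A's top levels[i] genes with
    list B's top levels[j]; the *_down fields are the mirrored
    co-downregulation map computed on bottom ranks.
    """

    step: int
    levels: np.ndarray  # rank cutoffs, clamped to N at the last level
    neglog10: np.ndarray
    counts: np.ndarray
    down_neglog10: np.ndarray
    down_counts: np.ndarray
    ranks_a: pd.Series  # gene -> rank in A (shared universe)
    ranks_b: pd.Series

    @property
    def n_genes(self) -> int:
        return len(self.ranks_a)


def _grid_counts(ra: np.ndarray, rb: np.ndarray, step: int, m: int) -> np.ndarray:
    binned = np.zeros((m, m), dtype=np.int64)
    ia = (ra - 1) // step
    ib = (rb - 1) // step
    np.add.at(binned, (ia, ib), 1)
    return binned.cumsum(axis=0).cumsum(axis=1)


def _score_grid(counts: np.ndarray, levels: np.ndarray, n: int) -> np.ndarray:
    out = np.empty(counts.shape, dtype=float)
    for i, s in enumerate(levels):
        for j, t in enumerate(levels):
            out[i, j] = neg_log10_from_ln(
                log_hypergeom_sf(int(counts[i, j]), n, int(s), int(t))
            )
    return out


def rrho_map(a: pd.DataFrame, b: pd.DataFrame, step: int | None = None) -> RrhoMap:
    """RRHO map between two ranked tables (see compute_ranking).

    Universes are intersected with a warning if they differ; ranks are
    recomputed within the shared universe preserving each table's order.
    Default step gives at most a 100 x 100 grid.
    """
    genes_a, genes_b = set(a.index), set(b.index)
    if genes_a != genes_b:
        warnings.warn(
            f"gene universes differ ({len(genes_a)} vs {len(genes_b)}); "
            "intersecting",
            stacklevel=2,
        )
        common = genes_a & genes_b
        a = a.loc[a.index.isin(common)]
        b = b.loc[b.index.isin(common)]
    n = len(a)
    if n == 0:
        raise ValueError("empty shared gene universe")
    # ranks within the shared universe, preserving each table's order
    ra = a["rank"].rank(method="first").astype(int)
    rb = b["rank"].rank(method="first").astype(int)
    rb = rb.reindex(ra.index)
    if step is None:
        step = max(1, n // 100)
    if step > n:
        raise ValueError(f"step {step} exceeds universe size {n}")
    m = math.ceil(n / step)
    levels = np.minimum(step * np.arange(1, m + 1), n)
    rav = ra.to_numpy()
    rbv = rb.to_numpy()
    counts = _grid_counts(rav, rbv, step, m)
    down_counts = _grid_counts(n + 1 - rav, n + 1 - rbv, step, m)
    return RrhoMap(
        step=step,
        levels=levels,
        neglog10=_score_grid(counts, levels, n),
        counts=counts,
        down_neglog10=_score_grid(down_counts, levels, n),
        down_counts=down_counts,
        ranks_a=ra,
        ranks_b=rb,
    )


def co_up_overlap_genes(rmap: RrhoMap) -> tuple[list[str], tuple[int, int], float]:
    """Overlap gene set at the co-up map's maximising cell.

    Ties are broken by the smallest s+t, then smallest s. Returns the sorted
    gene list, the (s, t) cutoffs, and the cell's -log10 p. An all-zero map
    returns an empty set with a warning.
    """
    m = rmap.neglog10
    if not (m > 0).any():
        warnings.warn("flat RRHO map; no overlap signal", stacklevel=2)
        return [], (int(rmap.levels[0]), int(rmap.levels[0])), 0.0
    best = None
    for i, s in enumerate(rmap.levels):
        for j, t in enumerate(rmap.levels):
            key = (-m[i, j], int(s) + int(t), int(s))
            if best is None or key < best[0]:
                best = (key, int(s), int(t), float(m[i, j]))
    _, s, t, val = best
    top_a = set(rmap.ranks_a.index[rmap.ranks_a <= s])
    top_b = set(rmap.ranks_b.index[rmap.ranks_b <= t])
    return sorted(top_a & top_b), (s, t), val


def map_to_tsv(rmap: RrhoMap, path) -> None:
    pd.DataFrame(rmap.neglog10, index=rmap.levels, columns=rmap.levels).to_csv(
        path, sep="\t"
    )


def plot_rrho(rmap: RrhoMap, path) -> None:
    """Heatmap of the co-up map (-log10 hypergeometric p)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(rmap.neglog10, origin="lower", cmap="viridis", aspect="auto")
    ax.set_xlabel("rank cutoff, list B")
    ax.set_ylabel("rank cutoff, list A")
    fig.colorbar(im, ax=ax, label="-log10 hypergeometric p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
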