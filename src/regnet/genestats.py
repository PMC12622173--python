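"""Gene-set overlap statistics and expression-bin-matched signature scoring.

The overlap test is an exact hypergeometric upper tail evaluated in log
space (lgamma arithmetic), so extreme significance levels remain
representable. Module scoring re-implements the standard single-cell
signature score: mean signature expression per cell minus the mean of
expression-bin-matched control genes, optionally aggregated over cluster
labels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import log_hypergeom_sf, neg_log10_from_ln

N_BINS = 24
N_CTRL = 100


@dataclass
class GeneSetOverlapResult:
    n_universe: int
    n_a: int
    n_b: int
    k_overlap: int
    p: float
    neg_log10_p: float
    overlap_genes: list[str]


def hypergeometric_overlap(
    universe: Iterable[str], a: Iterable[str], b: Iterable[str]
) -> GeneSetOverlapResult:
    """Upper-tail hypergeometric test of the overlap between two gene sets.

    Sets outside the universe are intersected with it (with a warning);
    p = P(X >= k) for X ~ Hypergeom(N, |a|, |b|).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    sa, sb = set(a), set(b)
    if not sa <= uni or not sb <= uni:
        extra = (sa | sb) - uni
        warnings.warn(
            f"{len(extra)} gene(s) outside the universe; intersecting",
            stacklevel=2,
        )
        sa &= uni
        sb &= uni
    k = len(sa & sb)
    log_p = log_hypergeom_sf(k, len(uni), len(sa), len(sb))
    return GeneSetOverlapResult(
        n_universe=len(uni),
        n_a=len(sa),
        n_b=len(sb),
        k_overlap=k,
        p=math.exp(log_p),
        neg_log10_p=neg_log10_from_ln(log_p),
        overlap_genes=sorted(sa & sb),
    )


@dataclass
class ModuleScoreResult:
    cell_scores: pd.Series  # per cell
    cluster_scores: pd.Series | None  # mean per cluster, when labels given
    signature_used: list[str]
    control_genes: dict[str, list[str]]  # signature gene -> sampled controls


def module_score(
    expr: pd.DataFrame,
    signature: Sequence[str],
    n_bins: int = N_BINS,
    n_ctrl: int = N_CTRL,
    seed: int = 0,
    clusters: pd.Series | None = None,
) -> ModuleScoreResult:
    """Signature score per cell against expression-matched controls.

    expr: cells x genes matrix. Genes are binned into n_bins by average
    expression across cells; each signature gene draws n_ctrl control genes
    (with replacement) from its bin, excluding signature genes (falling back
    to the nearest non-empty bin with a warning). Score per cell = mean
    signature expression - mean pooled-control expression. Deterministic for
    a fixed seed.
    """
    sig = [g for g in dict.fromkeys(signature) if g in expr.columns]
    if not sig:
        raise ValueError("signature has no genes in the expression matrix")
    rng = np.random.default_rng(seed)
    avg = expr.mean(axis=0)
    # rank-based binning keeps bins near-equal even with ties
    bins = pd.qcut(avg.rank(method="first"), q=min(n_bins, len(avg)), labels=False)
    sig_set = set(sig)
    eligible_by_bin: dict[int, list[str]] = {}
    for gene, bin_id in bins.items():
        if gene not in sig_set:
            eligible_by_bin.setdefault(int(bin_id), []).append(gene)
    control_genes: dict[str, list[str]] = {}
    pooled: list[str] = []
    for gene in sig:
        bin_id = int(bins[gene])
        pool = eligible_by_bin.get(bin_id, [])
        if not pool:
            # nearest non-empty bin
            candidates = sorted(eligible_by_bin, key=lambda b: (abs(b - bin_id), b))
            if not candidates:
                raise ValueError("no eligible control genes outside the signature")
            warnings.warn(
                f"bin {bin_id} has no eligible controls for {gene}; "
                f"using bin {candidates[0]}",
                stacklevel=2,
            )
            pool = eligible_by_bin[candidates[0]]
        draw = [pool[i] for i in rng.integers(0, len(pool), size=n_ctrl)]
        control_genes[gene] = draw
        pooled.extend(draw)
    sig_mean = expr[sig].mean(axis=1)
    ctrl_mean = expr[pooled].to_numpy().mean(axis=1)
    scores = pd.Series(sig_mean.to_numpy() - ctrl_mean, index=expr.index, name="score")
    cluster_scores = None
    if clusters is not None:
        cluster_scores = scores.groupby(clusters.reindex(scores.index)).mean()
    return ModuleScoreResult(scores, cluster_scores, sig, control_genes)


def read_gene_set(path: str | Path) -> list[str]:
    """Gene-set file: one symbol per line, '#' comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes


def write_gene_set(genes: Iterable[str], path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for g in genes:
            fh.write(f"{g}\n")
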