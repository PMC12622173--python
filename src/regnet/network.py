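"""Motif co-occurrence networks over active enhancers.

From resolved motif hits on an enhancer peak set, build a boolean
peak x motif occurrence matrix, test every motif pair for co-occurrence
beyond independence (one-sided Fisher exact on peak-level presence), retain
edges below a raw p threshold (default 0.001), enumerate maximal cliques
(default minimum size 3, i.e. more than two interconnected nodes), flag hub
motifs (degree above 10 by default), and annotate each clique's supporting
enhancers to their nearest genes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from . import intervals as iv

logger = logging.getLogger(__name__)

EDGE_ALPHA = 0.001
MIN_CLIQUE_SIZE = 3
HUB_DEGREE = 10


def build_occurrence_matrix(
    resolved_hits: pd.DataFrame,
    enhancer_peaks: iv.PeakSet,
    tf_whitelist: set[str] | None = None,
) -> pd.DataFrame:
    """Boolean peak x motif presence matrix from resolved hits.

    Columns are restricted to tf_whitelist when given (the expressed-TF
    motif list); all-false columns are dropped with a log line.
    """
    if len(enhancer_peaks) == 0:
        raise ValueError("empty enhancer peak set")
    peak_ids = enhancer_peaks.peak_ids
    motifs = sorted(set(resolved_hits["motif_id"])) if len(resolved_hits) else []
    if tf_whitelist is not None:
        motifs = [m for m in motifs if m in tf_whitelist]
    occ = pd.DataFrame(False, index=peak_ids, columns=motifs, dtype=bool)
    hits = resolved_hits[resolved_hits["peak_id"].isin(set(peak_ids))]
    if tf_whitelist is not None:
        hits = hits[hits["motif_id"].isin(tf_whitelist)]
    for peak_id, motif_id in hits[["peak_id", "motif_id"]].itertuples(index=False):
        occ.at[peak_id, motif_id] = True
    empty = [m for m in occ.columns if not occ[m].any()]
    if empty:
        logger.info("dropping %d motif column(s) with no presence: %s", len(empty), empty)
        occ = occ.drop(columns=empty)
    return occ


def test_edge(
    occ: pd.DataFrame, motif_a: str, motif_b: str
) -> tuple[int, float, float]:
    """One-sided Fisher exact test for co-occurrence of two motifs.

    2x2 table over peaks: (both, a only, b only, neither); the alternative is
    over-representation of joint presence. Returns (k_both, p, odds_ratio);
    odds ratio uses the Haldane 0.5 correction when any cell is zero.
    Degenerate columns (all true or all false) give p = 1 and a NaN odds
    ratio with a warning.
    """
    a = occ[motif_a].to_numpy()
    b = occ[motif_b].to_numpy()
    k11 = int(np.sum(a & b))
    k10 = int(np.sum(a & ~b))
    k01 = int(np.sum(~a & b))
    k00 = int(np.sum(~a & ~b))
    for name, col in ((motif_a, a), (motif_b, b)):
        if col.all() or not col.any():
            warnings.warn(
                f"degenerate presence column {name!r}; edge test undefined",
                stacklevel=2,
            )
            return k11, 1.0, float("nan")
    # canonical cell order so test_edge(a, b) == test_edge(b, a) bit-exactly
    lo, hi = sorted((k10, k01))
    p = float(fisher_exact([[k11, lo], [hi, k00]], alternative="greater").pvalue)
    if min(k11, k10, k01, k00) == 0:
        oratio = ((k11 + 0.5) * (k00 + 0.5)) / ((k10 + 0.5) * (k01 + 0.5))
    else:
        oratio = (k11 * k00) / (k10 * k01)
    return k11, p, float(oratio)


@dataclass
class CooccurrenceNetwork:
    """Significance-thresholded motif co-occurrence graph."""

    graph: nx.Graph
    edges: pd.DataFrame  # motif_a, motif_b, k_both, odds_ratio, p
    nodes: pd.DataFrame  # motif, presence_count, degree, is_hub
    edge_alpha: float
    hub_degree: int

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def hubs(self) -> list[str]:
        return sorted(self.nodes.index[self.nodes["is_hub"]])


def build_network(
    occ: pd.DataFrame,
    edge_alpha: float = EDGE_ALPHA,
    hub_degree: int = HUB_DEGREE,
    bh_correct: bool = False,
) -> CooccurrenceNetwork:
    """Test all motif pairs and keep edges with p < edge_alpha.

    The raw-p threshold is the default; bh_correct applies BH across pairs
    first and thresholds the adjusted p instead.
    """
    motifs = list(occ.columns)
    if len(motifs) < 2:
        raise ValueError("need at least two motifs to build a network")
    rows = []
    for i, ma in enumerate(motifs):
        for mb in motifs[i + 1 :]:
            k_both, p, oratio = test_edge(occ, ma, mb)
            rows.append((ma, mb, k_both, oratio, p))
    tested = pd.DataFrame(rows, columns=["motif_a", "motif_b", "k_both", "odds_ratio", "p"])
    pcol = tested["p"].to_numpy()
    if bh_correct and len(tested):
        pcol = multipletests(pcol, method="fdr_bh")[1]
    tested["p_effective"] = pcol
    kept = tested[tested["p_effective"] < edge_alpha].drop(columns="p_effective")
    kept = kept.reset_index(drop=True)
    g = nx.Graph()
    g.add_nodes_from(motifs)
    for row in kept.itertuples(index=False):
        g.add_edge(row.motif_a, row.motif_b, p=row.p, k_both=row.k_both)
    presence = occ.sum(axis=0)
    nodes = pd.DataFrame(
        {
            "presence_count": [int(presence[m]) for m in motifs],
            "degree": [g.degree[m] for m in motifs],
        },
        index=pd.Index(motifs, name="motif"),
    )
    nodes["is_hub"] = nodes["degree"] > hub_degree
    return CooccurrenceNetwork(g, kept, nodes, edge_alpha, hub_degree)


@dataclass
class Clique:
    """A maximal set of pairwise co-occurring motifs with its supporting
    enhancers and (optionally) their nearest target genes."""

    members: tuple[str, ...]
    supporting_peaks: list[str] = field(default_factory=list)
    target_genes: list[str] = field(default_factory=list)

    @property
    def frequency(self) -> int:
        return len(self.supporting_peaks)

    @property
    def size(self) -> int:
        return len(self.members)


def extract_maximal_cliques(
    net: CooccurrenceNetwork,
    occ: pd.DataFrame | None = None,
    min_size: int = MIN_CLIQUE_SIZE,
) -> list[Clique]:
    """All maximal cliques of the retained-edge graph with size >= min_size.

    Supporting peaks (rows of occ where every member is present) and
    frequency are filled when occ is given. Sorted by size desc, frequency
    desc, then lexicographic members.
    """
    cliques = []
    for members in nx.find_cliques(net.graph):
        if len(members) < min_size:
            continue
        members = tuple(sorted(members))
        supporting: list[str] = []
        if occ is not None:
            mask = occ[list(members)].all(axis=1)
            supporting = list(occ.index[mask])
        cliques.append(Clique(members, supporting_peaks=supporting))
    cliques.sort(key=lambda c: (-c.size, -c.frequency, c.members))
    return cliques


def clique_targets(
    clique: Clique, peaks: iv.PeakSet, tss: iv.TssAnnotation
) -> Clique:
    """Fill target_genes: deduplicated nearest-gene assignments of the
    clique's supporting enhancers, sorted."""
    if not clique.supporting_peaks:
        warnings.warn(
            f"clique {clique.members} has no supporting peaks; no targets",
            stacklevel=2,
        )
        return Clique(clique.members, [], [])
    sub = peaks.subset(clique.supporting_peaks)
    ann = iv.annotate_peaks_to_genes(sub, tss)
    genes = sorted({g for g in ann["nearest_gene"] if g is not None})
    return Clique(clique.members, list(clique.supporting_peaks), genes)


# ---------------------------------------------------------------------------
# tabular exports


def edges_to_tsv(net: CooccurrenceNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False)


def nodes_to_tsv(net: CooccurrenceNetwork, path) -> None:
    net.nodes.to_csv(path, sep="\t")


def cliques_to_tsv(cliques: list[Clique], path) -> None:
    rows = [
        {
            "members": ";".join(c.members),
            "size": c.size,
            "frequency": c.frequency,
            "supporting_peaks": ";".join(c.supporting_peaks),
            "target_genes": ";".join(c.target_genes),
        }
        for c in cliques
    ]
    pd.DataFrame(
        rows, columns=["members", "size", "frequency", "supporting_peaks", "target_genes"]
    ).to_csv(path, sep="\t", index=False)


def write_edge_list(net: CooccurrenceNetwork, path) -> None:
    """Plain edge list (motif_a<TAB>motif_b) for network viewers."""
    with open(path, "w") as fh:
        for row in net.edges.itertuples(index=False):
            fh.write(f"{row.motif_a}\t{row.motif_b}\n")
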