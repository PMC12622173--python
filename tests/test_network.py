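"""Occurrence matrices, Fisher edge tests, maximal cliques and targets."""

import math
from fractions import Fraction
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from regnet import intervals as iv, network as nw
from regnet.synthetic import SimulationConfig, generate_peak_sequences
from regnet.motifs import Pwm, scan_peaks
from .conftest import exact_hypergeom_sf


def hits_df(pairs):
    return pd.DataFrame(
        [{"peak_id": p, "motif_id": m, "offset": 0, "strand": "+", "score": 9.0,
          "length": 8} for p, m in pairs],
        columns=["peak_id", "motif_id", "offset", "strand", "score", "length"],
    )


def peakset(n, prefix="p"):
    ids = [f"{prefix}{i}" for i in range(n)]
    df = pd.DataFrame(
        {"chrom": "chrS", "start": np.arange(n) * 400, "end": np.arange(n) * 400 + 200},
        index=ids,
    )
    return iv.PeakSet(df)


def occ_from_bool(d):
    return pd.DataFrame(d).astype(bool)


def brute_force_maximal_cliques(graph, min_size):
    """Exhaustive all-subset maximality enumeration (<= 12 nodes)."""
    nodes = list(graph.nodes)
    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for sub in combinations(nodes, r):
            if all(graph.has_edge(a, b) for a, b in combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [c for c in cliques
               if not any(c < other for other in cliques)]
    return sorted(tuple(sorted(c)) for c in maximal)


class TestOccurrenceMatrix:
    def test_direct_tabulation(self):
        ps = peakset(3)
        occ = nw.build_occurrence_matrix(hits_df([("p0", "M1"), ("p1", "M1"), ("p1", "M2")]), ps)
        assert occ.values.tolist() == [[True, False], [True, True], [False, False]]

    def test_whitelist_filters_columns(self):
        ps = peakset(3)
        occ = nw.build_occurrence_matrix(
            hits_df([("p0", "M1"), ("p1", "M1"), ("p1", "M2")]), ps, tf_whitelist={"M2"}
        )
        assert list(occ.columns) == ["M2"]
        assert occ["M2"].tolist() == [False, True, False]

    def test_empty_peakset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nw.build_occurrence_matrix(hits_df([]), iv.PeakSet(
                pd.DataFrame(columns=["chrom", "start", "end"])))

    def test_planted_clique_column_sums(self):
        pwms = [Pwm.from_consensus(f"M{i}", c, p_consensus=0.99)
                for i, c in enumerate(["ACGTACGT", "TTGACCAA", "GGGCATTA"])]
        cfg = SimulationConfig(seed=5, n_peaks=1000, pwm_library=pwms,
                               planted_cliques=[(("M0", "M1", "M2"), 0.3)])
        peaks, seqs, truth = generate_peak_sequences(cfg)
        hits = scan_peaks(seqs, pwms)
        occ = nw.build_occurrence_matrix(hits, peaks)
        # 300 planted, each detected iff the sampled instance hits threshold
        for m in ("M0", "M1", "M2"):
            assert 180 <= occ[m].sum() <= 350


class TestEdgeTest:
    def test_matches_exact_hypergeometric_tail(self):
        # 100 peaks, a in 50, b in 50, both in 40
        occ = occ_from_bool({
            "a": [True] * 50 + [False] * 50,
            "b": [True] * 40 + [False] * 10 + [True] * 10 + [False] * 40,
        })
        k, p, oratio = nw.test_edge(occ, "a", "b")
        assert k == 40
        exact = exact_hypergeom_sf(40, 100, 50, 50)
        assert p == pytest.approx(float(exact), rel=1e-9)
        assert oratio == pytest.approx((40 * 40) / (10 * 10))

    def test_disjoint_presence_not_overrepresented(self):
        occ = occ_from_bool({
            "a": [True] * 30 + [False] * 70,
            "b": [False] * 30 + [True] * 30 + [False] * 40,
        })
        _, p, _ = nw.test_edge(occ, "a", "b")
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_independence_construction_not_significant(self):
        # both = a*b/N exactly: a=40, b=50, N=100, both=20
        a = [True] * 40 + [False] * 60
        b = [True] * 20 + [False] * 20 + [True] * 30 + [False] * 30
        occ = occ_from_bool({"a": a, "b": b})
        _, p, _ = nw.test_edge(occ, "a", "b")
        assert p > 0.1

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        occ = occ_from_bool({"a": rng.random(80) < 0.4, "b": rng.random(80) < 0.3})
        assert nw.test_edge(occ, "a", "b") == nw.test_edge(occ, "b", "a")

    def test_degenerate_column_warns_p_one(self):
        occ = occ_from_bool({"a": [True] * 10, "b": [True] * 5 + [False] * 5})
        with pytest.warns(UserWarning, match="degenerate"):
            k, p, oratio = nw.test_edge(occ, "a", "b")
        assert p == 1.0 and math.isnan(oratio)

    def test_haldane_correction_on_zero_cell(self):
        occ = occ_from_bool({
            "a": [True] * 5 + [False] * 5,
            "b": [True] * 5 + [False] * 5,
        })
        _, _, oratio = nw.test_edge(occ, "a", "b")
        assert oratio == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))


class TestBuildNetwork:
    def test_alpha_zero_empty_edges(self):
        rng = np.random.default_rng(1)
        occ = occ_from_bool({m: rng.random(50) < 0.5 for m in "abcd"})
        net = nw.build_network(occ, edge_alpha=0.0)
        assert net.n_edges == 0

    def test_planted_pair_edge_retained(self):
        rng = np.random.default_rng(2)
        n = 1000
        joint = rng.random(n) < 0.5
        occ = {"M1": joint.copy(), "M2": joint.copy()}
        for m in ("M3", "M4", "M5"):
            occ[m] = rng.random(n) < 0.1
        net = nw.build_network(occ_from_bool(occ))
        assert net.graph.has_edge("M1", "M2")

    def test_edge_count_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        occ = occ_from_bool({f"M{i}": rng.random(200) < 0.3 for i in range(6)})
        n_edges = [nw.build_network(occ, edge_alpha=a).n_edges
                   for a in (1e-6, 1e-3, 0.05, 0.5)]
        assert n_edges == sorted(n_edges)

    def test_column_permutation_destroys_edges(self):
        rng = np.random.default_rng(4)
        n = 500
        joint = rng.random(n) < 0.4
        base = {"M1": joint.copy(), "M2": joint.copy(),
                "M3": rng.random(n) < 0.2, "M4": rng.random(n) < 0.2}
        false_edges = 0
        n_perms = 40
        for _ in range(n_perms):
            permuted = {m: rng.permutation(v) for m, v in base.items()}
            false_edges += nw.build_network(occ_from_bool(permuted)).n_edges
        n_pairs = 6
        assert false_edges / n_perms <= 0.001 * n_pairs * 1.5 + 0.05

    def test_hub_flagging(self):
        g_occ = {}
        rng = np.random.default_rng(5)
        hub = rng.random(2000) < 0.5
        g_occ["HUB"] = hub
        for i in range(12):
            # each partner co-occurs strongly with HUB
            g_occ[f"M{i:02d}"] = hub & (rng.random(2000) < 0.8)
        net = nw.build_network(occ_from_bool(g_occ))
        assert "HUB" in net.hubs
        assert net.nodes.loc["HUB", "degree"] > 10


class TestMaximalCliques:
    def net_from_edges(self, nodes, edges):
        nodes = list(nodes)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        nodes_df = pd.DataFrame(
            {"presence_count": 0, "degree": [g.degree[n] for n in nodes]},
            index=pd.Index(nodes, name="motif"),
        )
        nodes_df["is_hub"] = False
        return nw.CooccurrenceNetwork(g, pd.DataFrame(), nodes_df, 0.001, 10)

    def test_textbook_graph(self):
        net = self.net_from_edges("ABCD", [("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")])
        cliques = nw.extract_maximal_cliques(net)
        assert [c.members for c in cliques] == [("A", "B", "C")]

    def test_complete_graph_single_clique(self):
        nodes = list("ABCDE")
        net = self.net_from_edges(nodes, list(combinations(nodes, 2)))
        cliques = nw.extract_maximal_cliques(net)
        assert [c.members for c in cliques] == [tuple(nodes)]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_subset_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(1 << 30)))
        g = nx.relabel_nodes(g, {i: f"M{i}" for i in range(n)})
        net = self.net_from_edges(list(g.nodes), list(g.edges))
        got = sorted(c.members for c in nw.extract_maximal_cliques(net, min_size=3))
        assert got == brute_force_maximal_cliques(g, 3)

    def test_supporting_peaks_and_frequency(self):
        occ = occ_from_bool({
            "A": [True, True, False, True],
            "B": [True, True, True, False],
            "C": [True, False, True, True],
        })
        occ.index = [f"p{i}" for i in range(4)]
        net = self.net_from_edges("ABC", [("A", "B"), ("B", "C"), ("A", "C")])
        cliques = nw.extract_maximal_cliques(net, occ)
        assert cliques[0].supporting_peaks == ["p0"]
        assert cliques[0].frequency == 1


class TestCliqueTargets:
    def test_targets_from_nearest_genes(self):
        ps = peakset(5)
        tss_rows = [(f"G{i}", "chrS", int(ps.intervals.iloc[i]["start"]) + 100 + 150, "+")
                    for i in range(5)]
        tss = iv.TssAnnotation(
            pd.DataFrame(tss_rows, columns=["gene", "chrom", "tss", "strand"]).set_index("gene")
        )
        clique = nw.Clique(("A", "B", "C"), supporting_peaks=["p0", "p1", "p2", "p3", "p4"])
        filled = nw.clique_targets(clique, ps, tss)
        assert filled.target_genes == [f"G{i}" for i in range(5)]

    def test_duplicate_targets_deduplicated(self):
        ps = peakset(2)
        # single gene nearest to both peaks
        tss = iv.TssAnnotation(pd.DataFrame(
            [("G", "chrS", 100, "+")], columns=["gene", "chrom", "tss", "strand"]
        ).set_index("gene"))
        clique = nw.Clique(("A", "B", "C"), supporting_peaks=["p0", "p1"])
        assert nw.clique_targets(clique, ps, tss).target_genes == ["G"]

    def test_no_supporting_peaks_warns(self):
        ps = peakset(2)
        tss = iv.TssAnnotation(pd.DataFrame(
            [("G", "chrS", 100, "+")], columns=["gene", "chrom", "tss", "strand"]
        ).set_index("gene"))
        with pytest.warns(UserWarning, match="no supporting"):
            filled = nw.clique_targets(nw.Clique(("A", "B")), ps, tss)
        assert filled.target_genes == []
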