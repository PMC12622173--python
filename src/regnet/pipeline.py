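"""End-to-end orchestration of the analysis stages.

Stage order follows the study design: peaks -> low-signal filter ->
differential test -> motif scan on the differential (active-enhancer) peaks
-> GC-background enrichment -> co-occurrence network -> maximal cliques ->
clique target genes, with the RRHO concordance and gene-set statistics as
parallel branches. Every stage writes plain-text tables into the run
directory; a manifest records input checksums, the seed and the constants,
and summary.json carries the per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import diffpeaks, genestats, intervals as iv, motifs as mo, network as nw, rrho
from .config import PipelineConfig
from .synthetic import SimulationConfig, write_bundle

logger = logging.getLogger(__name__)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _log_stage(name: str, **counts: Any) -> None:
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def sim_config_from_dict(spec: dict[str, Any], seed: int) -> SimulationConfig:
    """Build a SimulationConfig from the JSON `simulate` section.

    Motifs are given as {"motifs": {id: consensus}} with an optional
    "p_consensus"; planted pairs/cliques reference those ids.
    """
    spec = dict(spec)
    consensi = spec.pop("motifs", {})
    p_cons = spec.pop("p_consensus", 0.99)
    library = [
        mo.Pwm.from_consensus(mid, cons, p_consensus=p_cons)
        for mid, cons in consensi.items()
    ]
    pairs = [tuple(p) for p in spec.pop("planted_pairs", [])]
    cliques = [(tuple(m), f) for m, f in spec.pop("planted_cliques", [])]
    fc = [tuple(p) for p in spec.pop("planted_fc_peaks", [])]
    return SimulationConfig(
        seed=seed,
        pwm_library=library,
        planted_pairs=pairs,
        planted_cliques=cliques,
        planted_fc_peaks=fc,
        **spec,
    )


def demo_config(seed: int = 0) -> PipelineConfig:
    """The shipped demo: a planted 4-motif clique over 600 enhancers, fold
    changes on the first 200 peaks, and a concordant DE pair."""
    motifs = {
        "M_IRF": "AANTGAAA",
        "M_FLI": "ACAGGAAG",
        "M_MEF": "CTATTTAT",
        "M_MAF": "TGCTGACC",
        "M_SPI": "AGAGGAAG",
        "M_STA": "TTCCGGGA",
        "M_TGI": "TGTCAATC",
        "M_CEB": "ATTGCGCA",
        "M_RUN": "TGTGGTTT",
        "M_EGR": "GCGTGGGC",
    }
    motifs = {k: v.replace("N", "A") for k, v in motifs.items()}
    sim = {
        "n_peaks": 1500,
        "peak_length_bp": 200,
        "gc_fraction": 0.45,
        "motifs": motifs,
        "planted_cliques": [
            [["M_IRF", "M_FLI", "M_MEF", "M_MAF"], 0.4],
            [["M_SPI"], 0.05],
            [["M_STA"], 0.05],
            [["M_TGI"], 0.05],
        ],
        # two-sided differential signal on a modest fraction of peaks keeps
        # the median-column-sum normalization assumption valid
        "planted_fc_peaks": [[i, 2.5] for i in range(100)]
        + [[i, -2.5] for i in range(100, 200)],
        "n_samples_per_condition": 4,
        "nb_mean": 100.0,
        "nb_dispersion": 0.1,
        "de_n_genes": 4000,
        "de_true_fraction": 0.1,
        "de_shared_fraction": 0.5,
    }
    return PipelineConfig(seed=seed, simulate=sim)


def run_full(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage; returns the run directory.

    When `config.simulate` is set, the input bundle is generated first into
    <out_dir>/inputs and the config's paths are pointed at it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed}

    if config.simulate:
        sim = sim_config_from_dict(config.simulate, config.seed)
        paths = write_bundle(sim, out / "inputs")
        for key in (
            "fasta bed counts groups motifs tss de_a de_b expression clusters signature"
        ).split():
            setattr(config, key, str(paths[key]))
        _log_stage("simulate", n_peaks=sim.n_peaks, n_genes=sim.de_n_genes)
        summary["simulate"] = {"n_peaks": sim.n_peaks, "de_n_genes": sim.de_n_genes}

    config.validate_paths(["fasta", "bed", "counts", "groups", "motifs", "tss"])
    peaks = iv.read_bed(config.bed)
    sequences = mo.read_fasta(config.fasta)
    counts = iv.read_counts_tsv(config.counts)
    groups = dict(
        line.split("\t")
        for line in Path(config.groups).read_text().splitlines()
        if line.strip()
    )
    pwms = mo.read_homer_motifs(config.motifs)
    tss = iv.read_tss_tsv(config.tss)

    thresholds = diffpeaks.Thresholds(
        min_tag_count=config.min_tag_count,
        fc_threshold=config.fc_threshold,
        alpha=config.alpha,
    )
    diff_dir = out / "diff"
    diff_dir.mkdir(exist_ok=True)
    retained = diffpeaks.filter_low_signal(counts, thresholds)
    _log_stage("filter", peaks_in=len(counts), peaks_retained=len(retained))
    summary["filter"] = {"peaks_in": len(counts), "peaks_retained": len(retained)}

    result = diffpeaks.differential_test(retained, groups, thresholds)
    result.to_csv(diff_dir / "differential.tsv", sep="\t")
    up_ids = list(result.index[result["call"] == "up_in_b"])
    down_ids = list(result.index[result["call"] == "down_in_b"])
    iv.write_bed(peaks.subset(up_ids), diff_dir / "up.bed") if up_ids else (
        diff_dir / "up.bed"
    ).write_text("")
    iv.write_bed(peaks.subset(down_ids), diff_dir / "down.bed") if down_ids else (
        diff_dir / "down.bed"
    ).write_text("")
    _log_stage("differential", up=len(up_ids), down=len(down_ids), ns=len(result) - len(up_ids) - len(down_ids))
    summary["differential"] = {"up": len(up_ids), "down": len(down_ids)}

    # active-enhancer set: differential up peaks (all retained when empty)
    enhancer_ids = up_ids if up_ids else list(retained.index)
    enh_seqs = {pid: sequences[pid] for pid in enhancer_ids if pid in sequences}

    motif_dir = out / "motifs"
    motif_dir.mkdir(exist_ok=True)
    hits = mo.scan_peaks(enh_seqs, pwms)
    hits.to_csv(motif_dir / "hits.tsv", sep="\t", index=False)
    background = mo.generate_gc_background(enh_seqs, seed=config.seed)
    bg_hits = mo.scan_peaks(background, pwms)
    enrichment = mo.motif_enrichment(
        hits, bg_hits, len(enh_seqs), len(background),
        motif_ids=[p.motif_id for p in pwms],
    )
    enrichment.to_csv(motif_dir / "enrichment.tsv", sep="\t", index=False)
    _log_stage("scan", enhancers=len(enh_seqs), hits=len(hits), background=len(background))
    summary["scan"] = {"enhancers": len(enh_seqs), "hits": int(len(hits))}
    summary["enrichment"] = {
        "top_motif": str(enrichment.iloc[0]["motif_id"]) if len(enrichment) else None
    }

    net_dir = out / "network"
    net_dir.mkdir(exist_ok=True)
    occ = nw.build_occurrence_matrix(hits, peaks.subset(enhancer_ids))
    if occ.shape[1] >= 2:
        net = nw.build_network(occ, edge_alpha=config.edge_alpha, hub_degree=config.hub_degree)
        cliques = nw.extract_maximal_cliques(net, occ, min_size=config.min_clique_size)
        cliques = [nw.clique_targets(c, peaks, tss) for c in cliques]
        nw.edges_to_tsv(net, net_dir / "edges.tsv")
        nw.nodes_to_tsv(net, net_dir / "nodes.tsv")
        nw.write_edge_list(net, net_dir / "edges.txt")
        nw.cliques_to_tsv(cliques, net_dir / "cliques.tsv")
        summary["network"] = {
            "n_edges": net.n_edges,
            "n_hubs": len(net.hubs),
            "n_cliques": len(cliques),
            "largest_clique": max((c.size for c in cliques), default=0),
        }
        _log_stage("network", **summary["network"])
    else:
        nw.cliques_to_tsv([], net_dir / "cliques.tsv")
        summary["network"] = {"n_edges": 0, "n_hubs": 0, "n_cliques": 0, "largest_clique": 0}
        _log_stage("network", skipped="fewer than two motif columns")

    if config.de_a and config.de_b:
        rrho_dir = out / "rrho"
        rrho_dir.mkdir(exist_ok=True)
        de_a = pd.read_csv(config.de_a, sep="\t", index_col=0)
        de_b = pd.read_csv(config.de_b, sep="\t", index_col=0)
        ranked_a = rrho.compute_ranking(de_a)
        ranked_b = rrho.compute_ranking(de_b)
        rmap = rrho.rrho_map(ranked_a, ranked_b, step=config.rrho_step)
        rrho.map_to_tsv(rmap, rrho_dir / "map.tsv")
        rrho.plot_rrho(rmap, rrho_dir / "map.png")
        overlap, (s, t), val = rrho.co_up_overlap_genes(rmap)
        genestats.write_gene_set(
            overlap, rrho_dir / "co_up_genes.txt", header=f"cell s={s} t={t} neglog10p={val:.4f}"
        )
        summary["rrho"] = {
            "n_genes": rmap.n_genes,
            "map_max_neglog10_p": float(np.max(rmap.neglog10)),
            "argmax_cell": [s, t],
            "n_co_up_genes": len(overlap),
        }
        _log_stage("rrho", **{k: summary["rrho"][k] for k in ("n_genes", "n_co_up_genes")})

        # gene-set branch: overlap of the two tables' significant up genes
        up_a = set(de_a.index[(de_a["padj"] < config.alpha) & (de_a["log2fc"] > 0)])
        up_b = set(de_b.index[(de_b["padj"] < config.alpha) & (de_b["log2fc"] > 0)])
        ov = genestats.hypergeometric_overlap(set(de_a.index), up_a, up_b)
        summary["geneset_overlap"] = {
            "n_universe": ov.n_universe,
            "n_a": ov.n_a,
            "n_b": ov.n_b,
            "k_overlap": ov.k_overlap,
            "neg_log10_p": round(ov.neg_log10_p, 6),
        }
        _log_stage("geneset_overlap", k=ov.k_overlap)

    if config.expression and config.signature:
        expr = pd.read_csv(config.expression, sep="\t", index_col=0)
        signature = genestats.read_gene_set(config.signature)
        clusters = None
        if config.clusters:
            clusters = pd.read_csv(config.clusters, sep="\t", index_col=0)["cluster"]
        score = genestats.module_score(expr, signature, seed=config.seed, clusters=clusters)
        score_dir = out / "genestats"
        score_dir.mkdir(exist_ok=True)
        score.cell_scores.round(6).to_csv(score_dir / "cell_scores.tsv", sep="\t")
        if score.cluster_scores is not None:
            score.cluster_scores.round(6).to_csv(score_dir / "cluster_scores.tsv", sep="\t")
            summary["module_score"] = {
                k: round(float(v), 4) for k, v in score.cluster_scores.items()
            }
        _log_stage("module_score", cells=len(score.cell_scores))

    manifest = {
        "seed": config.seed,
        "constants": {
            "min_tag_count": config.min_tag_count,
            "fc_threshold": config.fc_threshold,
            "alpha": config.alpha,
            "edge_alpha": config.edge_alpha,
            "min_clique_size": config.min_clique_size,
            "hub_degree": config.hub_degree,
        },
        "inputs": {
            key: {"path": str(getattr(config, key)), "sha256": _sha256(getattr(config, key))}
            for key in (
                "fasta bed counts groups motifs tss de_a de_b expression clusters signature"
            ).split()
            if getattr(config, key) and Path(getattr(config, key)).exists()
        },
        "stages": sorted(summary.keys() - {"seed"}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return out
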