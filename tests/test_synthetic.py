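"""Ground-truth generators: GC control, plantings, counts and DE tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from regnet.motifs import Pwm, gc_fraction
from regnet.synthetic import (
    SimulationConfig,
    SizingError,
    generate_count_table,
    generate_paired_de_tables,
    generate_peak_sequences,
    generate_tss_table,
    write_bundle,
)


def library():
    return [
        Pwm.from_consensus("M1", "ACGTACGT", p_consensus=0.99),
        Pwm.from_consensus("M2", "TTGACCAA", p_consensus=0.99),
        Pwm.from_consensus("M3", "GGGCATTA", p_consensus=0.99),
    ]


class TestPeakSequences:
    def test_empirical_gc_tracks_parameter(self):
        cfg = SimulationConfig(seed=0, n_peaks=1000, peak_length_bp=200, gc_fraction=0.5)
        _, seqs, _ = generate_peak_sequences(cfg)
        gc = gc_fraction("".join(seqs.values()))
        assert 0.48 <= gc <= 0.52

    def test_planted_pair_present_in_every_peak(self):
        cfg = SimulationConfig(seed=1, n_peaks=50, pwm_library=library(),
                               planted_pairs=[("M1", "M2", 1.0)])
        _, seqs, truth = generate_peak_sequences(cfg)
        by_peak = {}
        for peak_id, motif_id, off, strand in truth.planted_hits:
            by_peak.setdefault(peak_id, []).append((motif_id, off))
        assert len(by_peak) == 50
        for peak_id, hits in by_peak.items():
            motifs = {m for m, _ in hits}
            assert motifs == {"M1", "M2"}
            # non-overlapping spans (all library motifs are 8 bp)
            spans = sorted((off, off + 8) for _, off in hits)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_planted_hits_inside_peaks(self):
        cfg = SimulationConfig(seed=2, n_peaks=100, peak_length_bp=60,
                               pwm_library=library(),
                               planted_cliques=[(("M1", "M2", "M3"), 0.5)])
        _, seqs, truth = generate_peak_sequences(cfg)
        for peak_id, motif_id, off, strand in truth.planted_hits:
            assert 0 <= off and off + 8 <= 60
            assert strand in "+-"

    def test_planted_instance_written_into_sequence(self):
        # with a (near-)deterministic PWM the planted occurrence is the consensus
        lib = [Pwm.from_probabilities(
            "M1",
            [[1 if b == c else 0 for b in "ACGT"] for c in "ACGTACGT"],
            pseudocount=1e-12,
        )]
        cfg = SimulationConfig(seed=3, n_peaks=20, pwm_library=lib,
                               planted_cliques=[(("M1",), 1.0)])
        _, seqs, truth = generate_peak_sequences(cfg)
        from regnet.motifs import reverse_complement

        for peak_id, _, off, strand in truth.planted_hits:
            written = seqs[peak_id][off : off + 8]
            assert written == ("ACGTACGT" if strand == "+" else
                               reverse_complement("ACGTACGT"))

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(seed=4, n_peaks=30, pwm_library=library(),
                               planted_pairs=[("M1", "M3", 0.5)])
        out1 = generate_peak_sequences(cfg)
        out2 = generate_peak_sequences(cfg)
        assert out1[1] == out2[1]
        assert out1[2].planted_hits == out2[2].planted_hits

    def test_peak_too_short_rejected(self):
        with pytest.raises(SizingError):
            SimulationConfig(seed=5, n_peaks=5, peak_length_bp=6, pwm_library=library())

    def test_oversubscribed_peak_rejected(self):
        lib = [Pwm.from_consensus(f"M{i}", "ACGTACGTACGT", p_consensus=0.99)
               for i in range(4)]
        cfg = SimulationConfig(seed=6, n_peaks=5, peak_length_bp=30, pwm_library=lib,
                               planted_cliques=[(tuple(f"M{i}" for i in range(4)), 1.0)])
        with pytest.raises(SizingError):
            generate_peak_sequences(cfg)


class TestCountTable:
    def test_null_ratio_near_one(self):
        cfg = SimulationConfig(seed=0, n_peaks=1000, nb_mean=50)
        peaks, _, _ = generate_peak_sequences(cfg)
        counts = generate_count_table(cfg, peaks)
        a = counts[[c for c in counts if c.startswith("A")]].mean(axis=1)
        b = counts[[c for c in counts if c.startswith("B")]].mean(axis=1)
        ratio = b.mean() / a.mean()
        assert 0.9 <= ratio <= 1.1

    def test_poisson_limit_at_zero_dispersion(self):
        cfg = SimulationConfig(seed=1, n_peaks=2000, nb_mean=50, nb_dispersion=0.0,
                               n_samples_per_condition=2)
        peaks, _, _ = generate_peak_sequences(cfg)
        counts = generate_count_table(cfg, peaks)
        col = counts["A_1"].to_numpy()
        assert np.var(col) / np.mean(col) == pytest.approx(1.0, abs=0.15)

    def test_planted_fold_change_realized(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_peaks=100, nb_mean=100,
                                   planted_fc_peaks=[(0, 3.0)])
            peaks, _, _ = generate_peak_sequences(cfg)
            counts = generate_count_table(cfg, peaks)
            row = counts.iloc[0]
            lfc = np.log2(row[4:].mean() / row[:4].mean())
            if 2.5 <= lfc <= 3.5:
                hits += 1
        assert hits >= 18

    def test_bad_peak_index_rejected(self):
        cfg = SimulationConfig(seed=2, n_peaks=10, planted_fc_peaks=[(10, 1.0)])
        peaks, _, _ = generate_peak_sequences(cfg)
        with pytest.raises(ValueError, match="out of range"):
            generate_count_table(cfg, peaks)


class TestPairedDeTables:
    def test_universe_contract(self):
        cfg = SimulationConfig(seed=0, de_n_genes=500)
        a, b, _ = generate_paired_de_tables(cfg)
        assert len(a) == len(b) == 500
        assert not a.index.has_duplicates
        assert set(a.index) == set(b.index)

    def test_full_sharing_zero_noise_identical_rankings(self):
        from regnet.rrho import compute_ranking

        cfg = SimulationConfig(seed=1, de_n_genes=400, de_shared_fraction=1.0,
                               de_noise_sd=0.0)
        a, b, _ = generate_paired_de_tables(cfg)
        ra = compute_ranking(a).sort_values("rank").index
        rb = compute_ranking(b).sort_values("rank").index
        assert list(ra) == list(rb)

    def test_zero_sharing_uncorrelated_metrics(self):
        cfg = SimulationConfig(seed=2, de_n_genes=10000, de_shared_fraction=0.0)
        a, b, _ = generate_paired_de_tables(cfg)
        ma = np.sign(a["log2fc"]) * (-np.log10(np.maximum(a["padj"], 1e-300)))
        mb = np.sign(b["log2fc"]) * (-np.log10(np.maximum(b["padj"], 1e-300)))
        rho = spearmanr(ma, mb.loc[ma.index]).statistic
        assert abs(rho) <= 0.1

    def test_truth_records_shared_genes(self):
        cfg = SimulationConfig(seed=3, de_n_genes=1000, de_true_fraction=0.1,
                               de_shared_fraction=0.5)
        a, b, truth = generate_paired_de_tables(cfg)
        assert len(truth.shared_up_genes) == 50
        for g in truth.shared_up_genes:
            assert truth.true_de_status["a"][g] == "up"
            assert truth.true_de_status["b"][g] == "up"


class TestBundle:
    def test_bundle_files_written_and_deterministic(self, tmp_path):
        cfg_kwargs = dict(seed=9, n_peaks=20, de_n_genes=100, pwm_library=library(),
                          planted_pairs=[("M1", "M2", 0.5)])
        p1 = write_bundle(SimulationConfig(**cfg_kwargs), tmp_path / "run1")
        p2 = write_bundle(SimulationConfig(**cfg_kwargs), tmp_path / "run2")
        for key in p1:
            assert p1[key].exists()
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_seed_changes_truth(self, tmp_path):
        base = dict(n_peaks=20, de_n_genes=100, pwm_library=library(),
                    planted_pairs=[("M1", "M2", 0.5)])
        _, _, t1 = generate_peak_sequences(SimulationConfig(seed=1, **base))
        _, _, t2 = generate_peak_sequences(SimulationConfig(seed=2, **base))
        assert t1.planted_hits != t2.planted_hits

    def test_tss_table_one_gene_per_peak(self):
        cfg = SimulationConfig(seed=0, n_peaks=25)
        peaks, _, _ = generate_peak_sequences(cfg)
        tss = generate_tss_table(cfg, peaks)
        assert len(tss) == 25


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_peaks=0)
    with pytest.raises(ValueError):
        SimulationConfig(gc_fraction=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(nb_mean=-1)
    with pytest.raises(ValueError):
        SimulationConfig(pwm_library=library(), planted_pairs=[("M1", "MX", 0.5)])
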