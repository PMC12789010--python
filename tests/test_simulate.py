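import numpy as np
import pytest

from chipcross.consensus import consensus_peaks
from chipcross.intervals import merge
from chipcross.motifs import classify_cooccurrence, scan_pwm
from chipcross.simulate import (
    MOTIF_A, MOTIF_B, SimulationConfig, simulate_accessibility, simulate_deg,
    simulate_genome, simulate_independent_sets, simulate_peaks_with_motifs,
    simulate_planted_overlap, simulate_replicates, simulate_set_pair,
    write_simulation,
)
from chipcross.stats import classify_accessibility, set_overlap_summary


def small_config(**kw):
    defaults = dict(seed=11, n_peaks=200, class_counts=(100, 40, 40, 20),
                    chrom_length=300_000)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateGenome:
    def test_shapes_and_determinism(self):
        cfg = SimulationConfig(seed=3, n_chroms=2, chrom_length=100_000)
        layout1, seqs1 = simulate_genome(cfg)
        layout2, seqs2 = simulate_genome(cfg)
        assert layout1.lengths == {"chr1": 100_000, "chr2": 100_000}
        assert all(len(s) == 100_000 for s in seqs1.values())
        assert seqs1 == seqs2  # byte-identical given the seed
        _, other = simulate_genome(SimulationConfig(seed=4, n_chroms=2,
                                                    chrom_length=100_000))
        assert other != seqs1

    def test_base_composition_near_uniform(self):
        cfg = SimulationConfig(seed=5, n_chroms=1, chrom_length=200_000)
        _, seqs = simulate_genome(cfg)
        seq = seqs["chr1"]
        for base in "ACGT":
            assert abs(seq.count(base) / len(seq) - 0.25) < 0.01


class TestSimulatePeaksWithMotifs:
    def test_planted_counts_recovered_exactly(self):
        cfg = small_config()
        layout, _ = simulate_genome(cfg)
        peaks, ha, hb, truth, _ = simulate_peaks_with_motifs(cfg, layout, None)
        table = classify_cooccurrence(peaks, ha, hb)
        assert table.counts == (100, 40, 40, 20)
        assert truth["motif_class"].value_counts().to_dict() == {
            "A_only": 100, "B_only": 40, "both": 40, "neither": 20}

    def test_peaks_non_overlapping(self):
        cfg = small_config()
        layout, _ = simulate_genome(cfg)
        peaks, *_ = simulate_peaks_with_motifs(cfg, layout, None)
        assert len(merge(peaks)) == len(peaks)

    def test_zero_sd_spacing_is_exact(self):
        cfg = small_config(spacing_sd=0.0)
        layout, _ = simulate_genome(cfg)
        _, _, _, truth, _ = simulate_peaks_with_motifs(cfg, layout, None)
        planted = truth.loc[truth.motif_class == "both", "planted_distance"]
        assert (planted == 25).all()

    def test_scanner_rediscovers_planted_instances(self):
        cfg = small_config()
        layout, seqs = simulate_genome(cfg)
        peaks, ha, hb, truth, seqs = simulate_peaks_with_motifs(
            cfg, layout, seqs)
        found_a = scan_pwm(peaks, seqs, MOTIF_A, MOTIF_A.max_score - 1e-6)
        found_b = scan_pwm(peaks, seqs, MOTIF_B, MOTIF_B.max_score - 1e-6)
        planted_a = {(h.interval.chrom, h.interval.start) for h in ha}
        planted_b = {(h.interval.chrom, h.interval.start) for h in hb}
        got_a = {(h.interval.chrom, h.interval.start) for h in found_a}
        got_b = {(h.interval.chrom, h.interval.start) for h in found_b}
        assert len(planted_a & got_a) >= 0.99 * len(planted_a)
        assert len(planted_b & got_b) >= 0.99 * len(planted_b)

    def test_capacity_error(self):
        cfg = SimulationConfig(seed=1, n_peaks=10_000,
                               class_counts=(10_000, 0, 0, 0),
                               n_chroms=1, chrom_length=100_000)
        layout, _ = simulate_genome(cfg)
        with pytest.raises(ValueError, match="capacity"):
            simulate_peaks_with_motifs(cfg, layout, None)


class TestSimulateReplicates:
    def _peaks(self, cfg):
        layout, _ = simulate_genome(cfg)
        peaks, *_ = simulate_peaks_with_motifs(cfg, layout, None)
        return peaks

    def test_perfect_detection_no_jitter_recovers_containers(self):
        cfg = small_config(detection_prob=1.0, jitter_sd=0.0)
        peaks = self._peaks(cfg)
        reps = simulate_replicates(peaks, cfg)
        got = consensus_peaks(reps, min_support=2)
        assert [(iv.chrom, iv.start, iv.end) for iv in got] == \
            [(iv.chrom, iv.start, iv.end) for iv in peaks]

    def test_zero_detection_empty(self):
        cfg = small_config(detection_prob=0.0)
        peaks = self._peaks(cfg)
        reps = simulate_replicates(peaks, cfg)
        assert all(len(r) == 0 for r in reps)
        assert len(consensus_peaks(reps, 2)) == 0

    def test_consensus_fraction_matches_binomial(self):
        # P(detected in >= 2 of 3) = 3 p^2 (1-p) + p^3
        cfg = SimulationConfig(seed=8, n_peaks=1000,
                               class_counts=(1000, 0, 0, 0),
                               detection_prob=0.8, jitter_sd=0.0)
        peaks = self._peaks(cfg)
        reps = simulate_replicates(peaks, cfg)
        got = consensus_peaks(reps, min_support=2)
        p = 0.8
        expected = 3 * p ** 2 * (1 - p) + p ** 3
        se = np.sqrt(expected * (1 - expected) / 1000)
        assert abs(len(got) / 1000 - expected) < 3 * se


class TestSimulateAccessibility:
    def test_all_accessible(self):
        cfg = small_config(accessible_prob={c: 1.0 for c in
                                            ("A_only", "B_only", "both", "neither")})
        layout, _ = simulate_genome(cfg)
        peaks, _, _, truth, _ = simulate_peaks_with_motifs(cfg, layout, None)
        atac, truth = simulate_accessibility(peaks, truth, cfg)
        _, props = classify_accessibility(peaks, atac)
        assert props["pct_ccr"] == 0.0

    def test_truth_labels_recovered_exactly(self):
        cfg = small_config()
        layout, _ = simulate_genome(cfg)
        peaks, _, _, truth, _ = simulate_peaks_with_motifs(cfg, layout, None)
        atac, truth = simulate_accessibility(peaks, truth, cfg)
        labels, _ = classify_accessibility(peaks, atac)
        for row in truth.itertuples():
            assert (labels[row.peak_id] == "accessible") == row.accessible

    def test_exact_counts_mode(self):
        cfg = small_config(ccr_count=43)
        layout, _ = simulate_genome(cfg)
        peaks, _, _, truth, _ = simulate_peaks_with_motifs(cfg, layout, None)
        atac, truth = simulate_accessibility(peaks, truth, cfg)
        _, props = classify_accessibility(peaks, atac)
        assert props["n_ccr"] == 43


class TestSimulateDeg:
    def _truth(self, cfg):
        layout, _ = simulate_genome(cfg)
        _, _, _, truth, _ = simulate_peaks_with_motifs(cfg, layout, None)
        return truth

    def test_all_up_class(self):
        cfg = small_config(
            p_up={c: (1.0 if c == "both" else 0.2)
                  for c in ("A_only", "B_only", "both", "neither")},
            p_down={c: 0.0 for c in ("A_only", "B_only", "both", "neither")})
        truth = self._truth(cfg)
        deg, truth = simulate_deg(truth, cfg)
        from chipcross.stats import deg_filter
        out = deg_filter(deg).set_index("gene")
        both_genes = truth.loc[truth.motif_class == "both", "gene"]
        assert (out.loc[both_genes, "direction"] == "up").all()

    def test_direction_matches_truth_after_filter(self):
        cfg = small_config()
        truth = self._truth(cfg)
        deg, truth = simulate_deg(truth, cfg)
        from chipcross.stats import deg_filter
        out = deg_filter(deg)
        merged = out.merge(truth, on="gene")
        assert (merged["direction"] == merged["planted_direction"]).all()


class TestSetAndOverlapGenerators:
    def test_exact_cardinalities(self):
        a, b = simulate_set_pair(30, 50, 12, seed=2)
        s = set_overlap_summary(a, b)
        assert (s.n_a, s.n_b, s.n_shared) == (30, 50, 12)
        assert s.pct_a_shared == pytest.approx(40.0)

    def test_zero_overlap(self):
        a, b = simulate_set_pair(10, 10, 0, seed=2)
        assert set_overlap_summary(a, b).n_shared == 0

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            simulate_set_pair(5, 5, 6, seed=1)

    def test_planted_containment_counts(self, toy_layout):
        from chipcross.intervals import overlap_count
        a, b = simulate_planted_overlap(toy_layout, 100, 200, 37, seed=9)
        assert overlap_count(a, b) == 37

    def test_independent_sets_shapes(self, toy_layout):
        a, b = simulate_independent_sets(toy_layout, 50, 60, seed=4)
        assert len(a) == 50 and len(b) == 60


def test_write_simulation_outputs(tmp_path):
    cfg = small_config()
    paths = write_simulation(cfg, tmp_path / "sim")
    for key in ("fasta", "chrom_sizes", "peaks", "rep1", "atac", "deg",
                "truth", "genes", "motif_hits"):
        assert paths[key].exists(), key
    import pandas as pd
    truth = pd.read_csv(paths["truth"], sep="\t")
    assert {"peak_id", "motif_class", "accessible", "gene",
            "planted_direction"} <= set(truth.columns)
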