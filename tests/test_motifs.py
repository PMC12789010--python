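import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chipcross.intervals import GenomicInterval, IntervalSet
from chipcross.motifs import (
    PWM, MotifHit, classify_cooccurrence, compare_cooccurrence,
    ks_two_sample, pair_distance_distribution, read_jaspar, read_meme,
    scan_pwm,
)
from conftest import brute_ks_d, brute_scan


def make_pwm(consensus="ACGTAC", dominant=97):
    counts = np.ones((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = dominant
    return PWM.from_counts("M1", counts)


def one_container(width=2000, chrom="chr1"):
    return IntervalSet([GenomicInterval(chrom, 0, width, name="c1")])


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestPWM:
    def test_invariants(self):
        with pytest.raises(ValueError):
            PWM("short", np.full((3, 4), 0.25))
        with pytest.raises(ValueError):
            PWM("neg", np.array([[1.0, 0, 0, 0]] * 4))  # zero probs

    def test_consensus_and_max_score(self):
        pwm = make_pwm("ACGT")
        assert pwm.consensus == "ACGT"
        assert pwm.score("ACGT") == pytest.approx(pwm.max_score)
        assert pwm.score("TTTT") < 0

    def test_non_acgt_scores_minus_inf(self):
        pwm = make_pwm("ACGT")
        assert pwm.score("ACNT") == float("-inf")


class TestScanPWM:
    def test_planted_consensus_found_at_offset(self, rng):
        pwm = make_pwm("GATTACAG")
        seq = random_seq(rng, 500)
        seq = seq[:100] + "GATTACAG" + seq[108:]
        hits = scan_pwm(one_container(500), {"chr1": seq}, pwm,
                        pwm.max_score - 1e-9)
        assert any(h.interval.start == 100 and h.strand == "+" for h in hits)

    def test_threshold_above_max_yields_nothing(self, rng):
        pwm = make_pwm()
        seq = random_seq(rng, 300)
        assert scan_pwm(one_container(300), {"chr1": seq}, pwm,
                        pwm.max_score + 1.0) == []

    def test_container_beyond_sequence_errors(self):
        pwm = make_pwm()
        with pytest.raises(ValueError, match="exceeds sequence bounds"):
            scan_pwm(one_container(2000), {"chr1": "ACGT" * 100}, pwm, 0.0)

    def test_matches_bruteforce_rescan(self, rng):
        for _ in range(20):
            w = int(rng.integers(4, 9))
            pwm = make_pwm(random_seq(rng, w), dominant=int(rng.integers(3, 50)))
            seq = random_seq(rng, 250)
            threshold = float(rng.uniform(-2, pwm.max_score))
            hits = scan_pwm(one_container(250), {"chr1": seq}, pwm, threshold)
            got = sorted((h.interval.start, h.strand, round(h.score, 9))
                         for h in hits)
            assert got == brute_scan(seq, pwm, threshold)

    def test_reverse_complement_mirror(self, rng):
        pwm = make_pwm("GATTAC")
        seq = random_seq(rng, 400)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        fwd = scan_pwm(one_container(400), {"chr1": seq}, pwm, 2.0)
        rev = scan_pwm(one_container(400), {"chr1": rc}, pwm, 2.0)
        n = len(seq)
        mirrored = sorted((n - h.interval.end, {"+": "-", "-": "+"}[h.strand],
                           round(h.score, 6)) for h in rev)
        assert mirrored == sorted((h.interval.start, h.strand,
                                   round(h.score, 6)) for h in fwd)

    def test_offsets_relative_to_container_start(self, rng):
        pwm = make_pwm("GATTACAG")
        seq = random_seq(rng, 1000)
        seq = seq[:700] + "GATTACAG" + seq[708:]
        containers = IntervalSet([GenomicInterval("chr1", 600, 900, name="c")])
        hits = scan_pwm(containers, {"chr1": seq}, pwm, pwm.max_score - 1e-9)
        assert any(h.interval.start == 700 for h in hits)


def hit(container_id, motif="A", start=0, width=10):
    return MotifHit(GenomicInterval("chr1", start, start + width),
                    motif, 5.0, "+", container_id)


def containers(n, width=300):
    return IntervalSet([
        GenomicInterval("chr1", i * 1000, i * 1000 + width, name=f"c{i}")
        for i in range(n)])


class TestCooccurrence:
    def test_single_a_only(self):
        c = containers(1)
        t = classify_cooccurrence(c, [hit("c0")], [])
        assert t.counts == (1, 0, 0, 0)

    def test_planted_printed_counts(self):
        # 1000 containers engineered to the printed class percentages
        c = containers(1000)
        ids = [f"c{i}" for i in range(1000)]
        hits_a = [hit(i) for i in ids[:593]] + [hit(i) for i in ids[690:861]]
        hits_b = [hit(i, "B") for i in ids[593:690]] + \
            [hit(i, "B") for i in ids[690:861]]
        t = classify_cooccurrence(c, hits_a, hits_b)
        assert t.counts == (593, 97, 171, 139)
        assert [round(p, 1) for p in t.percentages] == [59.3, 9.7, 17.1, 13.9]

    def test_order_and_duplicate_invariance(self, rng):
        c = containers(20)
        ids = [f"c{i}" for i in range(20)]
        hits_a = [hit(i) for i in ids[:12]]
        hits_b = [hit(i, "B") for i in ids[6:15]]
        base = classify_cooccurrence(c, hits_a, hits_b).counts
        shuffled = list(hits_a)
        rng.shuffle(shuffled)
        dup = shuffled + shuffled[:5]
        assert classify_cooccurrence(c, dup, hits_b).counts == base

    def test_unknown_container_errors(self):
        with pytest.raises(ValueError, match="unknown container"):
            classify_cooccurrence(containers(2), [hit("nope")], [])

    def test_counts_sum_to_total_and_percentages_to_100(self):
        c = containers(10)
        t = classify_cooccurrence(
            c, [hit(f"c{i}") for i in range(4)],
            [hit(f"c{i}", "B") for i in range(2, 7)])
        assert sum(t.counts) == t.total == 10
        assert sum(t.percentages) == pytest.approx(100.0)


class TestCompareCooccurrence:
    def test_identical_tables(self):
        from chipcross.motifs import CooccurrenceTable
        t = CooccurrenceTable(10, 10, 10, 10)
        res = compare_cooccurrence(t, t)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.dof == 3

    def test_closed_form(self):
        from chipcross.motifs import CooccurrenceTable
        x = CooccurrenceTable(20, 10, 10, 10)
        y = CooccurrenceTable(10, 20, 10, 10)
        res = compare_cooccurrence(x, y)
        obs = np.array([x.counts, y.counts], dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert res.statistic == pytest.approx(((obs - expected) ** 2 / expected).sum())

    def test_all_zero_class_errors(self):
        from chipcross.motifs import CooccurrenceTable
        x = CooccurrenceTable(20, 10, 10, 0)
        y = CooccurrenceTable(10, 20, 10, 0)
        with pytest.raises(ValueError, match="pool"):
            compare_cooccurrence(x, y)


class TestSpacing:
    def test_center_to_center_arithmetic(self):
        c = containers(1)
        a = [hit("c0", "A", start=100, width=10)]   # center 105
        b = [hit("c0", "B", start=125, width=10)]   # center 130
        dist = pair_distance_distribution(c, a, b)
        assert dist.distances == [25]

    def test_empty_when_no_shared_container(self):
        c = containers(2)
        dist = pair_distance_distribution(c, [hit("c0")], [hit("c1", "B")])
        assert len(dist) == 0

    def test_nearest_pair_selected(self):
        c = containers(1)
        a = [hit("c0", "A", start=0, width=10),
             hit("c0", "A", start=100, width=10)]
        b = [hit("c0", "B", start=120, width=10)]
        dist = pair_distance_distribution(c, a, b)
        assert dist.distances == [20]

    def test_edge_convention_clips_overlaps_to_zero(self):
        c = containers(1)
        a = [hit("c0", "A", start=100, width=20)]
        b = [hit("c0", "B", start=110, width=20)]
        dist = pair_distance_distribution(c, a, b, convention="edge")
        assert dist.distances == [0]

    def test_planted_normal_spacing_mode(self, rng):
        centers_a = rng.integers(200, 800, size=500)
        offsets = np.rint(rng.normal(25, 2, size=500)).astype(int)
        c = IntervalSet([GenomicInterval("chr1", i * 2000, i * 2000 + 1000,
                                         name=f"c{i}") for i in range(500)])
        a, b = [], []
        for i, (ca, off) in enumerate(zip(centers_a, offsets)):
            base = i * 2000
            a.append(hit(f"c{i}", "A", start=base + ca - 5, width=10))
            b.append(hit(f"c{i}", "B", start=base + ca + off - 5, width=10))
        dist = pair_distance_distribution(c, a, b)
        lo, hi = dist.mode_bin
        assert lo <= 25 < hi


class TestKSTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3, 3], [1, 2, 3, 3])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, p = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0
        assert p < 0.2

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=40),
           st.lists(st.floats(-100, 100), min_size=1, max_size=40))
    def test_symmetric_and_bounded(self, x, y):
        d1, p1 = ks_two_sample(x, y)
        d2, p2 = ks_two_sample(y, x)
        assert d1 == pytest.approx(d2)
        assert p1 == pytest.approx(p2)
        assert 0.0 <= d1 <= 1.0
        assert 0.0 < p1 <= 1.0

    def test_matches_ecdf_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, size=int(rng.integers(1, 60))).tolist()
            y = rng.normal(0.5, 2, size=int(rng.integers(1, 60))).tolist()
            d, _ = ks_two_sample(x, y)
            assert d == pytest.approx(brute_ks_d(x, y))

    def test_large_sample_asymptotic_p(self, rng):
        x = rng.normal(0, 1, size=400)
        y = rng.normal(0, 1, size=400)
        d, p = ks_two_sample(x, y)
        n_eff = 400 * 400 / 800
        from scipy.stats import kstwobign
        assert p == pytest.approx(float(kstwobign.sf(math.sqrt(n_eff) * d)))


class TestPWMReaders:
    def test_jaspar_bracketed(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(
            ">MA0001.1 TEST\n"
            "A [ 10  1  1  1 ]\n"
            "C [  1 10  1  1 ]\n"
            "G [  1  1 10  1 ]\n"
            "T [  1  1  1 10 ]\n"
        )
        [pwm] = read_jaspar(p)
        assert pwm.motif_id == "MA0001.1"
        assert pwm.consensus == "ACGT"
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_meme_minimal(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.3 C 0.2 G 0.2 T 0.3\n\n"
            "MOTIF M2\n"
            "letter-probability matrix: alength= 4 w= 4 nsites= 20\n"
            "0.97 0.01 0.01 0.01\n0.01 0.97 0.01 0.01\n"
            "0.01 0.01 0.97 0.01\n0.01 0.01 0.01 0.97\n"
        )
        [pwm] = read_meme(p)
        assert pwm.consensus == "ACGT"
        assert pwm.background[0] == pytest.approx(0.3)
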