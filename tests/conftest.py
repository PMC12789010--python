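import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from chipcross.intervals import GenomicInterval, IntervalSet, GenomeLayout

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept separate from the implementations)


def brute_union_bases(intervals) -> set[tuple[str, int]]:
    """Per-base membership of the union of an interval collection."""
    bases = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            bases.add((iv.chrom, pos))
    return bases


def brute_overlap_count(a, b, min_bp=1) -> int:
    """O(|A|*|B|) pairwise overlap counting."""
    count = 0
    for iva in a:
        for ivb in b:
            if iva.chrom != ivb.chrom:
                continue
            if min(iva.end, ivb.end) - max(iva.start, ivb.start) >= min_bp:
                count += 1
                break
    return count


def brute_consensus_bases(replicates, k) -> set[tuple[str, int]]:
    """Bases covered by >= k distinct replicates (per-base support oracle)."""
    support: dict[tuple[str, int], int] = {}
    for rep in replicates:
        for base in brute_union_bases(rep):
            support[base] = support.get(base, 0) + 1
    return {base for base, n in support.items() if n >= k}


def brute_scan(seq: str, pwm, threshold: float):
    """Exhaustive per-position, per-strand log-odds rescan."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    hits = []
    w = pwm.width
    for off in range(len(seq) - w + 1):
        window = seq[off:off + w].upper()
        if any(b not in "ACGT" for b in window):
            continue
        fwd = pwm.score(window)
        if fwd >= threshold:
            hits.append((off, "+", round(fwd, 9)))
        rc = "".join(comp[b] for b in reversed(window))
        rev = pwm.score(rc)
        if rev >= threshold:
            hits.append((off, "-", round(rev, 9)))
    return sorted(hits)


def brute_ks_d(x, y) -> float:
    """ECDF sup oracle evaluated at every sample point of both samples."""
    xs, ys = sorted(x), sorted(y)
    best = 0.0
    for t in xs + ys:
        fx = sum(1 for v in xs if v <= t) / len(xs)
        fy = sum(1 for v in ys if v <= t) / len(ys)
        best = max(best, abs(fx - fy))
    return best


def random_interval_set(rng, n, chroms=("chr1", "chr2"), max_pos=10_000,
                        max_len=200, label="") -> IntervalSet:
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len + 1))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_layout():
    return GenomeLayout({"chr1": 1_000_000, "chr2": 1_000_000})
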