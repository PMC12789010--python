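"""Deterministic synthetic-data generators with planted structure.

Every input the pipeline consumes can be generated here: a uniform-base
genome, non-overlapping TF-bound peaks carrying planted motif instances with
controlled co-occurrence classes and spacing, noisy replicate peak sets,
class-conditional ATAC accessibility, class-conditional differential
expression, and id-set pairs with exact overlap cardinalities.  A truth table
records every planted label so downstream recovery can be asserted without
re-simulation.

All generators are pure functions of the configuration (seed included); the
seed is mandatory, never the clock.  Stage sub-seeds are ``seed + stage
offset`` (genome +0, peaks +1, replicates +2, accessibility +3, DEG +4), so
stages are independently reproducible.

Peaks are placed on an equal-slot grid: each chromosome is divided into as
many equal slots as peaks assigned to it and each peak gets a uniform offset
inside its slot.  This guarantees non-overlapping peaks without rejection
loops while keeping positions irregular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from chipcross.intervals import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    write_bed,
    write_chrom_sizes,
)
from chipcross.motifs import PWM, MotifHit

__all__ = [
    "SimulationConfig", "MOTIF_A", "MOTIF_B",
    "simulate_genome", "simulate_peaks_with_motifs", "simulate_replicates",
    "simulate_accessibility", "simulate_deg", "simulate_set_pair",
    "simulate_planted_overlap", "simulate_independent_sets",
    "write_simulation",
]

CLASSES = ("A_only", "B_only", "both", "neither")

_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _motif_counts(consensus: str, dominant: int = 97) -> np.ndarray:
    counts = np.ones((len(consensus), 4))
    for i, base in enumerate(consensus):
        counts[i, "ACGT".index(base)] = dominant
    return counts


#: PRDM1-like motif (consensus GAAAGTGAAAGT) — the "A" motif of the pipeline.
MOTIF_A = PWM.from_counts("PRDM1", _motif_counts("GAAAGTGAAAGT"))
#: RUNX-like motif (consensus TGTGGTTTGT) — the "B" motif of the pipeline.
MOTIF_B = PWM.from_counts("RUNX", _motif_counts("TGTGGTTTGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline inputs.

    Defaults plant the motif-class composition reported for IL-2-cultured NK
    cells (59.3% / 9.7% / 17.1% / 13.9% at 1000 peaks), a 25 bp mean motif
    spacing, three replicates at 80% detection, class-conditional
    accessibility with PRDM1-only sites least accessible, and a higher
    up-regulated fraction among doubly-bound genes.
    """

    seed: int
    # genome
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    # peaks & motifs
    n_peaks: int = 1000
    peak_width: int = 300
    class_counts: tuple[int, int, int, int] = (593, 97, 171, 139)
    class_mode: str = "counts"  # "counts" plants exact cardinalities;
    # "fractions" draws each peak's class independently from the normalized
    # counts, giving binomial sampling noise for calibration studies.
    spacing_mean: float = 25.0
    spacing_sd: float = 5.0
    # replicates
    n_replicates: int = 3
    detection_prob: float = 0.8
    jitter_sd: float = 10.0
    # accessibility
    accessible_prob: dict = field(default_factory=lambda: {
        "A_only": 0.6, "B_only": 0.9, "both": 0.75, "neither": 0.7})
    ccr_count: int | None = None  # exact-counts mode: exactly this many CCRs
    atac_width: int = 500
    # differential expression
    p_up: dict = field(default_factory=lambda: {
        "A_only": 0.2, "B_only": 0.4, "both": 0.6, "neither": 0.3})
    p_down: dict = field(default_factory=lambda: {
        "A_only": 0.3, "B_only": 0.2, "both": 0.1, "neither": 0.3})
    effect: float = 1.5  # |log2 fold change| of significant genes

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.class_mode not in ("counts", "fractions"):
            raise ValueError("class_mode must be 'counts' or 'fractions'")
        if self.class_mode == "counts" and sum(self.class_counts) != self.n_peaks:
            raise ValueError("class_counts must sum to n_peaks")
        for cls in CLASSES:
            pu = self.p_up.get(cls, 0.0)
            pdn = self.p_down.get(cls, 0.0)
            if pu + pdn > 1:
                raise ValueError(f"P(up)+P(down) > 1 for class {cls}")
            if not (0 <= self.accessible_prob.get(cls, 1.0) <= 1):
                raise ValueError(f"accessible_prob out of [0,1] for {cls}")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to integer, halves away from zero (cross-language reproducible)."""
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def _layout(config: SimulationConfig) -> GenomeLayout:
    return GenomeLayout({
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)})


def simulate_genome(config: SimulationConfig) -> tuple[GenomeLayout, dict[str, str]]:
    """Uniform-base genome: layout plus one random sequence per chromosome."""
    rng = np.random.default_rng(config.seed)
    layout = _layout(config)
    seqs = {}
    for chrom, length in layout.lengths.items():
        codes = rng.integers(0, 4, size=length)
        seqs[chrom] = bytes(_BYTES[codes]).decode("ascii")
    return layout, seqs


def _place_peaks(layout: GenomeLayout, n_peaks: int, width: int,
                 rng: np.random.Generator) -> list[GenomicInterval]:
    chroms = list(layout.lengths)
    lengths = np.array([layout.lengths[c] for c in chroms], dtype=float)
    # proportional allocation by chromosome length, largest remainder
    quota = n_peaks * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    rem = n_peaks - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    peaks = []
    idx = 0
    for chrom, n_c in zip(chroms, counts):
        if n_c == 0:
            continue
        slot = layout.lengths[chrom] // n_c
        if slot < width + 2:
            raise ValueError(
                f"requested peaks exceed genome capacity on {chrom} "
                f"(slot {slot} bp < peak width {width} bp)"
            )
        offsets = rng.integers(0, slot - width + 1, size=n_c)
        for j in range(n_c):
            start = j * slot + int(offsets[j])
            peaks.append(GenomicInterval(chrom, start, start + width,
                                         name=f"peak{idx:05d}"))
            idx += 1
    return peaks


def simulate_peaks_with_motifs(
    config: SimulationConfig,
    layout: GenomeLayout,
    seqs: dict[str, str] | None = None,
) -> tuple[IntervalSet, list[MotifHit], list[MotifHit], pd.DataFrame,
           dict[str, str] | None]:
    """Non-overlapping peaks with planted motif classes and spacings.

    Plants exact per-class counts (``class_mode="counts"``) or samples each
    peak's class independently (``"fractions"``).  For "both" peaks, the A-B
    center distance is drawn Normal(spacing_mean, spacing_sd), rounded, and
    truncated at the wider motif's width so instances never overlap.  When
    ``seqs`` is given, the consensus strings are written into the sequence
    (overwriting background bases) so a scanner at the consensus-score
    threshold rediscovers every planted instance; the mutated sequences are
    returned.
    """
    rng = np.random.default_rng(config.seed + 1)
    peaks = _place_peaks(layout, config.n_peaks, config.peak_width, rng)

    if config.class_mode == "counts":
        class_per_peak = np.repeat(np.arange(4), config.class_counts)
    else:
        frac = np.asarray(config.class_counts, dtype=float)
        class_per_peak = rng.choice(4, size=config.n_peaks, p=frac / frac.sum())
    class_per_peak = rng.permutation(class_per_peak) \
        if config.class_mode == "counts" else class_per_peak

    mutable = {c: bytearray(s, "ascii") for c, s in seqs.items()} \
        if seqs is not None else None
    wa, wb = MOTIF_A.width, MOTIF_B.width
    min_dist = max(wa, wb)
    hits_a: list[MotifHit] = []
    hits_b: list[MotifHit] = []
    rows = []

    def plant(peak: GenomicInterval, pwm: PWM, center: int) -> MotifHit:
        start = center - pwm.width // 2
        if mutable is not None:
            mutable[peak.chrom][start:start + pwm.width] = \
                pwm.consensus.encode("ascii")
        iv = GenomicInterval(peak.chrom, start, start + pwm.width,
                             name=pwm.motif_id)
        return MotifHit(iv, pwm.motif_id, pwm.max_score, "+", peak.id)

    for peak, cls_idx in zip(peaks, class_per_peak):
        cls = CLASSES[cls_idx]
        distance = None
        if cls == "A_only":
            hits_a.append(plant(peak, MOTIF_A, peak.center))
        elif cls == "B_only":
            hits_b.append(plant(peak, MOTIF_B, peak.center))
        elif cls == "both":
            for _ in range(1000):
                d = int(_round_half_away(
                    np.array([rng.normal(config.spacing_mean,
                                         config.spacing_sd)]))[0])
                if d >= min_dist and peak.center + d + wb // 2 < peak.end - 1:
                    break
            else:
                raise ValueError("could not draw a feasible motif spacing")
            distance = d
            a_center = peak.center - d // 2
            b_center = a_center + d
            hits_a.append(plant(peak, MOTIF_A, a_center))
            hits_b.append(plant(peak, MOTIF_B, b_center))
        rows.append({
            "peak_id": peak.id, "chrom": peak.chrom, "start": peak.start,
            "end": peak.end, "motif_class": cls, "planted_distance": distance,
            "class_mode": config.class_mode,
        })
    truth = pd.DataFrame(rows)
    out_seqs = ({c: bytes(b).decode("ascii") for c, b in mutable.items()}
                if mutable is not None else None)
    return IntervalSet(peaks, label="peaks"), hits_a, hits_b, truth, out_seqs


def simulate_replicates(
    containers: IntervalSet, config: SimulationConfig
) -> list[IntervalSet]:
    """Replicate peak sets: per-peak Bernoulli detection plus boundary jitter.

    Each replicate keeps each peak independently with ``detection_prob`` and
    jitters both boundaries by rounded Normal(0, jitter_sd), clipped so the
    interval stays non-empty and non-negative.
    """
    if not (0 < config.detection_prob <= 1) and config.detection_prob != 0:
        raise ValueError("detection_prob must be in [0, 1]")
    rng = np.random.default_rng(config.seed + 2)
    peaks = list(containers)
    replicates = []
    for r in range(config.n_replicates):
        kept = rng.random(len(peaks)) < config.detection_prob
        jit = _round_half_away(
            rng.normal(0.0, config.jitter_sd, size=(len(peaks), 2)))
        ivs = []
        for keep, peak, (j0, j1) in zip(kept, peaks, jit):
            if not keep:
                continue
            start = max(0, peak.start + int(j0))
            end = max(start + 1, peak.end + int(j1))
            ivs.append(GenomicInterval(peak.chrom, start, end, name=peak.name))
        replicates.append(IntervalSet(ivs, label=f"rep{r + 1}"))
    return replicates


def simulate_accessibility(
    containers: IntervalSet,
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[IntervalSet, pd.DataFrame]:
    """ATAC peaks overlapping a class-conditional subset of bound sites.

    Probability mode emits an overlapping ATAC peak for each container with
    its class's ``accessible_prob``.  Exact-counts mode (``ccr_count`` set)
    instead picks exactly that many containers, uniformly, to be CCRs.  The
    returned truth table gains an ``accessible`` column.
    """
    rng = np.random.default_rng(config.seed + 3)
    class_by_id = dict(zip(truth["peak_id"], truth["motif_class"]))
    peaks = list(containers)
    n = len(peaks)
    if config.ccr_count is not None:
        if config.ccr_count > n:
            raise ValueError("ccr_count exceeds the number of sites")
        accessible = np.ones(n, dtype=bool)
        accessible[rng.choice(n, size=config.ccr_count, replace=False)] = False
    else:
        probs = np.array([config.accessible_prob[class_by_id[p.id]]
                          for p in peaks])
        accessible = rng.random(n) < probs
    atac = []
    acc_by_id: dict[str, bool] = {}
    half = config.atac_width // 2
    for peak, acc in zip(peaks, accessible):
        acc_by_id[peak.id] = bool(acc)
        if acc:
            # truncate at the bound-site boundaries so an ATAC peak never
            # leaks into a neighboring site: labels are planted exactly
            start = max(peak.start, peak.center - half)
            end = min(peak.end, peak.center - half + config.atac_width)
            atac.append(GenomicInterval(peak.chrom, start, end))
    truth = truth.assign(accessible=truth["peak_id"].map(acc_by_id))
    return IntervalSet(atac, label="atac"), truth


def simulate_deg(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DEG table with class-conditional direction, one gene per bound site.

    up/down genes get log2fc = ±effect and padj ~ U(0, 0.05); ns genes get
    log2fc ~ Normal(0, 0.1) and padj ~ U(0.05, 1).  Returns (deg_table,
    truth with gene and direction columns).
    """
    rng = np.random.default_rng(config.seed + 4)
    n = len(truth)
    genes = [f"G{i:05d}" for i in range(n)]
    u = rng.random(n)
    p_up = truth["motif_class"].map(config.p_up).to_numpy(dtype=float)
    p_down = truth["motif_class"].map(config.p_down).to_numpy(dtype=float)
    direction = np.where(u < p_up, "up",
                         np.where(u < p_up + p_down, "down", "ns"))
    log2fc = np.where(direction == "up", config.effect,
                      np.where(direction == "down", -config.effect,
                               rng.normal(0.0, 0.1, size=n)))
    padj = np.where(direction == "ns",
                    rng.uniform(0.05, 1.0, size=n),
                    rng.uniform(0.0, 0.05, size=n))
    deg = pd.DataFrame({"gene": genes, "log2fc": log2fc, "padj": padj})
    truth = truth.assign(gene=genes, planted_direction=direction)
    return deg, truth


def simulate_set_pair(
    size_a: int, size_b: int, overlap: int, seed: int,
    prefix: str = "ID",
) -> tuple[set[str], set[str]]:
    """Two synthetic id sets with exact cardinalities |A|, |B|, |A ∩ B|."""
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed min(|A|, |B|)")
    rng = np.random.default_rng(seed)
    universe = size_a + size_b  # enough distinct labels
    ids = rng.permutation(universe)
    shared = {f"{prefix}{i:06d}" for i in ids[:overlap]}
    a_only = {f"{prefix}{i:06d}" for i in ids[overlap:size_a]}
    b_only = {f"{prefix}{i:06d}"
              for i in ids[size_a:size_a + size_b - overlap]}
    return shared | a_only, shared | b_only


def simulate_planted_overlap(
    layout: GenomeLayout,
    n_a: int,
    n_b: int,
    n_contained: int,
    seed: int,
    width_a: int = 200,
    width_b: int = 1000,
) -> tuple[IntervalSet, IntervalSet]:
    """Interval sets where exactly ``n_contained`` of A lie inside B intervals
    and the rest of A avoids B entirely.  Requires width_a <= width_b."""
    if n_contained > n_a:
        raise ValueError("n_contained cannot exceed n_a")
    if width_a > width_b:
        raise ValueError("width_a must be <= width_b for containment")
    rng = np.random.default_rng(seed)
    b_ivs = _place_peaks(layout, n_b, width_b, rng)
    b_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b_ivs:
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    a_ivs = []
    hosts = rng.choice(len(b_ivs), size=n_contained,
                       replace=n_contained > len(b_ivs))
    for i, h in enumerate(hosts):
        host = b_ivs[int(h)]
        start = int(rng.integers(host.start, host.end - width_a + 1))
        a_ivs.append(GenomicInterval(host.chrom, start, start + width_a,
                                     name=f"a_in{i:05d}"))
    chroms = list(layout.lengths)
    n_free = n_a - n_contained
    placed = 0
    attempts = 0
    while placed < n_free:
        attempts += 1
        if attempts > 1000 * max(1, n_free):
            raise ValueError("could not place background intervals off B")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, layout.lengths[chrom] - width_a + 1))
        end = start + width_a
        if any(iv.start < end and iv.end > start
               for iv in b_by_chrom.get(chrom, [])):
            continue
        a_ivs.append(GenomicInterval(chrom, start, end,
                                     name=f"a_out{placed:05d}"))
        placed += 1
    return (IntervalSet(a_ivs, label="A"), IntervalSet(b_ivs, label="B"))


def simulate_independent_sets(
    layout: GenomeLayout,
    n_a: int,
    n_b: int,
    seed: int,
    width_a: int = 200,
    width_b: int = 1000,
) -> tuple[IntervalSet, IntervalSet]:
    """Two interval sets placed independently, iid uniform per interval.

    Each interval's chromosome is drawn with probability proportional to
    length and its start uniformly over valid positions — exactly the shuffle
    null's placement model, so observed overlaps are genuinely null.
    Intervals may overlap within a set.
    """
    rng = np.random.default_rng(seed)
    chroms = list(layout.lengths)
    lens = np.array([layout.lengths[c] for c in chroms], dtype=float)
    out_sets = []
    for label, n, width in (("A", n_a, width_a), ("B", n_b, width_b)):
        probs = lens / lens.sum()
        picks = rng.choice(len(chroms), size=n, p=probs)
        ivs = []
        for i, ci in enumerate(picks):
            chrom = chroms[int(ci)]
            start = int(rng.integers(0, layout.lengths[chrom] - width + 1))
            ivs.append(GenomicInterval(chrom, start, start + width,
                                       name=f"{label.lower()}{i:05d}"))
        out_sets.append(IntervalSet(ivs, label=label))
    return out_sets[0], out_sets[1]


def write_simulation(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run the full generator chain and write FASTA, chrom.sizes, BEDs, the
    DEG TSV and the truth table into ``out_dir``.  Returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout, seqs = simulate_genome(config)
    peaks, hits_a, hits_b, truth, seqs = simulate_peaks_with_motifs(
        config, layout, seqs)
    replicates = simulate_replicates(peaks, config)
    atac, truth = simulate_accessibility(peaks, truth, config)
    deg, truth = simulate_deg(truth, config)

    paths: dict[str, Path] = {}
    fasta = out / "genome.fa"
    with fasta.open("w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    paths["fasta"] = fasta
    paths["chrom_sizes"] = out / "genome.chrom.sizes"
    write_chrom_sizes(layout, paths["chrom_sizes"])
    paths["peaks"] = out / "peaks.bed"
    write_bed(peaks, paths["peaks"])
    for i, rep in enumerate(replicates, start=1):
        paths[f"rep{i}"] = out / f"rep{i}.bed"
        write_bed(rep, paths[f"rep{i}"])
    paths["atac"] = out / "atac.bed"
    write_bed(atac, paths["atac"])
    hits_set = IntervalSet(
        [h.interval for h in hits_a] + [h.interval for h in hits_b])
    paths["motif_hits"] = out / "motif_hits.bed"
    write_bed(hits_set, paths["motif_hits"])
    paths["deg"] = out / "deg.tsv"
    deg.to_csv(paths["deg"], sep="\t", index=False)
    # one gene per bound site, TSS at the peak center, body = the peak:
    # lets the annotation/assignment stages run on simulated data alone
    paths["genes"] = out / "genes.tsv"
    with paths["genes"].open("w") as fh:
        fh.write("#gene_id\tchrom\ttss\tstrand\tbody\n")
        for row in truth.itertuples():
            center = (row.start + row.end) // 2
            fh.write(f"{row.gene}\t{row.chrom}\t{center}\t+\t"
                     f"{row.start}-{row.end}\n")
    paths["truth"] = out / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
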