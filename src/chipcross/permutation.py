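"""Genome-aware random shuffling of interval sets and empirical overlap
significance.

The null model re-places every query interval with its length preserved, start
drawn uniformly over the valid positions of its own chromosome
(``keep_chrom=True``, analogous to ``bedtools shuffle -chrom``) or of a
chromosome drawn with probability proportional to length.  Shuffled intervals
may overlap one another (bedtools default); a no-self-overlap mode exists but
is off by default.  Empirical p uses the add-one rule (r+1)/(N+1), which is
never zero.

Sub-seeds are derived as ``seed + shuffle_index`` so runs are reproducible and
parallelizable by index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from chipcross.intervals import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    _merged_arrays,
    _count_union_overlaps,
    overlap_count,
)

__all__ = ["PermutationResult", "shuffle_intervals", "permutation_overlap_test"]

_MAX_REDRAWS = 1000


@dataclass
class PermutationResult:
    observed: int
    null_counts: list[int]
    p_value: float
    n_shuffles: int
    seed: int
    direction: str

    def summary(self) -> dict:
        null = np.asarray(self.null_counts)
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
            "direction": self.direction,
            "null_mean": float(null.mean()),
            "null_sd": float(null.std(ddof=1)) if len(null) > 1 else 0.0,
            "null_min": int(null.min()),
            "null_max": int(null.max()),
        }


def _grouped_lengths(a: IntervalSet) -> list[tuple[str, np.ndarray]]:
    return [
        (chrom, np.fromiter((len(iv) for iv in a.per_chrom(chrom)),
                            dtype=np.int64))
        for chrom in a.chromosomes
    ]


def _intersects_excluded(excluded: IntervalSet, chrom: str, start: int,
                         end: int) -> bool:
    return any(iv.start < end and iv.end > start
               for iv in excluded.per_chrom(chrom))


def _shuffle_starts_keep_chrom(
    grouped: Sequence[tuple[str, np.ndarray]],
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Vectorized placement (no exclusion handling): one draw per chromosome
    group, in sorted chromosome order.  Returns (chrom, starts, lengths)."""
    out = []
    for chrom, lengths in grouped:
        if chrom not in layout.lengths:
            raise ValueError(f"chromosome {chrom!r} absent from layout")
        chrom_len = layout.lengths[chrom]
        if lengths.size and int(lengths.max()) > chrom_len:
            raise ValueError(
                f"an interval of length {int(lengths.max())} exceeds "
                f"chromosome {chrom} ({chrom_len} bp)"
            )
        starts = rng.integers(0, chrom_len - lengths + 1)
        out.append((chrom, starts, lengths))
    return out


def shuffle_intervals(
    a: IntervalSet,
    layout: GenomeLayout,
    seed: int,
    keep_chrom: bool = True,
    avoid_excluded: bool = True,
    no_self_overlap: bool = False,
) -> IntervalSet:
    """Re-place every interval of ``a`` at a random position, lengths preserved.

    Deterministic given ``seed``.  With excluded regions (and
    ``avoid_excluded``), placements intersecting them are redrawn up to 1000
    times before an error naming the interval.
    """
    rng = np.random.default_rng(seed)
    excluded = layout.excluded if (avoid_excluded and layout.excluded) else None

    if keep_chrom and excluded is None and not no_self_overlap:
        placed = _shuffle_starts_keep_chrom(_grouped_lengths(a), layout, rng)
        out = [
            GenomicInterval(chrom, int(s), int(s + ln))
            for chrom, starts, lengths in placed
            for s, ln in zip(starts, lengths)
        ]
        return IntervalSet(out, label=f"{a.label}.shuffled" if a.label else "shuffled")

    chrom_names = list(layout.lengths)
    chrom_lens = np.array([layout.lengths[c] for c in chrom_names], dtype=float)
    taken: dict[str, list[tuple[int, int]]] = {}
    out = []
    for iv in a:
        length = len(iv)
        if keep_chrom:
            candidates = [iv.chrom]
            if layout.lengths.get(iv.chrom, 0) < length:
                raise ValueError(
                    f"interval {iv.id} does not fit on its chromosome")
        else:
            fits = [c for c, L in zip(chrom_names, chrom_lens) if L >= length]
            if not fits:
                raise ValueError(
                    f"interval {iv.id} is longer than every permitted chromosome")
            candidates = fits
        weights = np.array([layout.lengths[c] for c in candidates], dtype=float)
        weights /= weights.sum()
        for _ in range(_MAX_REDRAWS):
            chrom = candidates[int(rng.choice(len(candidates), p=weights))] \
                if len(candidates) > 1 else candidates[0]
            start = int(rng.integers(0, layout.lengths[chrom] - length + 1))
            end = start + length
            if excluded is not None and _intersects_excluded(
                    excluded, chrom, start, end):
                continue
            if no_self_overlap and any(
                    s < end and e > start for s, e in taken.get(chrom, [])):
                continue
            taken.setdefault(chrom, []).append((start, end))
            out.append(GenomicInterval(chrom, start, end))
            break
        else:
            raise ValueError(
                f"no valid placement for interval {iv.id} after "
                f"{_MAX_REDRAWS} redraws"
            )
    return IntervalSet(out, label=f"{a.label}.shuffled" if a.label else "shuffled")


def permutation_overlap_test(
    a: IntervalSet,
    b: IntervalSet,
    layout: GenomeLayout,
    n_shuffles: int = 1000,
    seed: int = 0,
    direction: str = "greater",
    min_bp: int = 1,
    keep_chrom: bool = True,
) -> PermutationResult:
    """Empirical significance of ``overlap_count(a, b)`` under the shuffle null.

    ``a`` (the query) is shuffled; ``b`` is never shuffled.  The i-th shuffle
    uses sub-seed ``seed + i``.  p = (1 + #{null >= observed}) / (1 + N) for
    ``direction="greater"`` (<= for "less").
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    observed = overlap_count(a, b, min_bp=min_bp)

    fast = (min_bp == 1 and keep_chrom
            and (layout.excluded is None or len(layout.excluded) == 0))
    null_counts: list[int] = []
    if fast:
        grouped = _grouped_lengths(a)
        b_arrays = _merged_arrays(b)
        for chrom, lengths in grouped:  # validate fit once
            if chrom not in layout.lengths:
                raise ValueError(f"chromosome {chrom!r} absent from layout")
            if lengths.size and int(lengths.max()) > layout.lengths[chrom]:
                raise ValueError(
                    f"an interval exceeds chromosome {chrom}")
        for i in range(n_shuffles):
            rng = np.random.default_rng(seed + i)
            count = 0
            for chrom, starts, lengths in _shuffle_starts_keep_chrom(
                    grouped, layout, rng):
                if chrom in b_arrays:
                    m_start, m_end = b_arrays[chrom]
                    count += _count_union_overlaps(
                        starts, starts + lengths, m_start, m_end)
            null_counts.append(count)
    else:
        for i in range(n_shuffles):
            shuffled = shuffle_intervals(a, layout, seed + i,
                                         keep_chrom=keep_chrom)
            null_counts.append(overlap_count(shuffled, b, min_bp=min_bp))

    null = np.asarray(null_counts)
    if direction == "greater":
        r = int((null >= observed).sum())
    else:
        r = int((null <= observed).sum())
    p = (r + 1) / (n_shuffles + 1)
    return PermutationResult(observed, null_counts, p, n_shuffles, seed,
                             direction)
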