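"""Genomic-interval data model, interval algebra, and BED/narrowPeak I/O.

Coordinates are 0-based half-open throughout (BED convention).  Book-ended
intervals ([100,200) and [200,300)) do not overlap but do merge at
``max_gap=0``.  Chromosome names are compared as exact strings; no aliasing.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicInterval", "IntervalSet", "GenomeLayout",
    "read_bed", "write_bed", "read_chrom_sizes", "write_chrom_sizes",
    "merge", "overlap_count", "BedParseError",
]

_STRANDS = {"+", "-", "."}

#: BED dialects understood by :func:`read_bed`, mapped to column counts.
BED_DIALECTS = {
    "bed3": 3,
    "bed4": 4,
    "bed5": 5,
    "bed6": 6,
    "narrowPeak": 10,
}


class BedParseError(ValueError):
    """A BED/narrowPeak line violated the format or an interval invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic range ``[start, end)`` on ``chrom``.

    ``attrs`` carries auxiliary columns (e.g. narrowPeak signalValue, pValue,
    qValue and the absolute 0-based summit position).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    attrs: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Shared base count with ``other`` (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def id(self) -> str:
        """Stable identifier: the name if set, else ``chrom:start-end``."""
        return self.name if self.name else f"{self.chrom}:{self.start}-{self.end}"


class IntervalSet:
    """Intervals grouped per chromosome, sorted by (start, end).

    Iteration yields intervals chromosome by chromosome (lexicographic
    chromosome order), sorted within each chromosome.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.label = label
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort(key=lambda iv: (iv.start, iv.end))

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def per_chrom(self, chrom: str) -> list[GenomicInterval]:
        return self._by_chrom.get(chrom, [])

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chromosomes:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        lab = f" label={self.label!r}" if self.label else ""
        return f"<IntervalSet n={len(self)} chroms={len(self._by_chrom)}{lab}>"

    def total_bp(self) -> int:
        """Base coverage of the union of all members."""
        return sum(len(iv) for iv in merge(self))


@dataclass
class GenomeLayout:
    """Ordered map chromosome -> length (bp), plus optional excluded regions."""

    lengths: dict[str, int]
    excluded: IntervalSet | None = None

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        if self.excluded is not None:
            for iv in self.excluded:
                limit = self.lengths.get(iv.chrom)
                if limit is None or iv.end > limit:
                    raise ValueError(
                        f"excluded region {iv.chrom}:{iv.start}-{iv.end} "
                        "lies outside the genome layout"
                    )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def total_bp(self) -> int:
        return sum(self.lengths.values())


# ---------------------------------------------------------------------------
# I/O


def _parse_bed_line(line: str, n_cols: int, dialect: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < n_cols:
        raise BedParseError(
            f"line {lineno}: expected >= {n_cols} tab-separated columns for "
            f"{dialect}, got {len(fields)}"
        )
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
    name = fields[3] if n_cols >= 4 and fields[3] != "." else None
    score: float | None = None
    if n_cols >= 5 and fields[4] != ".":
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-numeric score") from exc
    strand = fields[5] if n_cols >= 6 else "."
    attrs: tuple[tuple[str, object], ...] = ()
    if dialect == "narrowPeak":
        try:
            summit_offset = int(fields[9])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-integer summit offset") from exc
        # summit offset -1 means "not called"; otherwise store absolute 0-based
        summit = None if summit_offset == -1 else start + summit_offset
        attrs = (
            ("signalValue", float(fields[6])),
            ("pValue", float(fields[7])),
            ("qValue", float(fields[8])),
            ("summit", summit),
        )
    try:
        return GenomicInterval(chrom, start, end, name, score, strand, attrs)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from exc


def read_bed(path: str | Path, dialect: str = "bed6", label: str = "") -> IntervalSet:
    """Read a BED3..BED6 or ENCODE narrowPeak file into an :class:`IntervalSet`.

    Lines are validated eagerly; a malformed line raises :class:`BedParseError`
    naming the 1-based line number.  Input order is not required; the returned
    set is sorted.  For ``bed6`` files with fewer trailing columns the missing
    ones default (name None, score None, strand '.').
    """
    if dialect not in BED_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {sorted(BED_DIALECTS)}"
        )
    n_cols = BED_DIALECTS[dialect]
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            # allow short trailing columns for the bed6 convenience dialect
            effective = min(n_cols, len(fields)) if dialect == "bed6" else n_cols
            if effective < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            intervals.append(_parse_bed_line(line, effective, dialect, lineno))
    return IntervalSet(intervals, label=label or path.stem)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write an :class:`IntervalSet` as BED6 (tab-separated, '.' placeholders)."""
    path = Path(path)
    with path.open("w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{score}\t{iv.strand}\n"
            )


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a two-column (name, length) chromosome-sizes TSV."""
    lengths: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"line {lineno}: expected 'name<TAB>length'")
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer length") from exc
    return GenomeLayout(lengths)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, length in layout.lengths.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# Interval algebra


def merge(intervals: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Fuse intervals whose gap is <= ``max_gap`` bp into their union.

    With ``max_gap=0`` book-ended intervals fuse (half-open adjacency).  The
    output is the minimal sorted, non-overlapping set covering the same bases.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[GenomicInterval] = []
    for chrom in intervals.chromosomes:
        run_start = run_end = None
        for iv in intervals.per_chrom(chrom):
            if run_start is None:
                run_start, run_end = iv.start, iv.end
            elif iv.start <= run_end + max_gap:
                run_end = max(run_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, run_start, run_end))
                run_start, run_end = iv.start, iv.end
        if run_start is not None:
            out.append(GenomicInterval(chrom, run_start, run_end))
    return IntervalSet(out, label=intervals.label)


def _merged_arrays(b: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) arrays of the merged set, for fast queries."""
    merged = merge(b)
    out = {}
    for chrom in merged.chromosomes:
        ivs = merged.per_chrom(chrom)
        out[chrom] = (
            np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs)),
            np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs)),
        )
    return out


def overlap_count(a: IntervalSet, b: IntervalSet, min_bp: int = 1) -> int:
    """Number of intervals of ``a`` sharing >= ``min_bp`` bases with >= 1
    interval of ``b``.  Each ``a`` interval is counted at most once.

    The default ``min_bp=1`` matches common bedtools semantics (one shared
    base counts as overlap).
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if min_bp == 1:
        # union suffices: >=1 shared base with some interval iff with the union
        total = 0
        for chrom, (starts, ends) in _merged_arrays(b).items():
            a_ivs = a.per_chrom(chrom)
            if not a_ivs:
                continue
            a_start = np.fromiter((iv.start for iv in a_ivs), dtype=np.int64)
            a_end = np.fromiter((iv.end for iv in a_ivs), dtype=np.int64)
            total += int(_count_union_overlaps(a_start, a_end, starts, ends))
        return total
    # general case: a per-interval scan against b sorted by start
    total = 0
    for chrom in a.chromosomes:
        b_ivs = b.per_chrom(chrom)
        if not b_ivs:
            continue
        b_starts = [iv.start for iv in b_ivs]
        for iv in a.per_chrom(chrom):
            # any b with b.start < iv.end could overlap; walk candidates
            hi = bisect.bisect_left(b_starts, iv.end)
            for bi in b_ivs[:hi]:
                if min(iv.end, bi.end) - max(iv.start, bi.start) >= min_bp:
                    total += 1
                    break
    return total


def _count_union_overlaps(
    a_start: np.ndarray, a_end: np.ndarray,
    m_start: np.ndarray, m_end: np.ndarray,
) -> int:
    """Count a-intervals intersecting a merged (sorted, disjoint) set."""
    if len(m_start) == 0 or len(a_start) == 0:
        return 0
    idx = np.searchsorted(m_start, a_end, side="left")
    hit = (idx > 0) & (m_end[np.maximum(idx - 1, 0)] > a_start)
    return int(hit.sum())
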