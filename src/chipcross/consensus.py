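"""Consensus peaks across replicates and region/gene annotation.

Consensus is defined at base resolution by default: a consensus peak is a
maximal genomic run where at least ``min_support`` distinct replicates have
coverage.  This reading of "present in at least k samples" is
order-independent and reproducible; a peak-level alternative (keep replicate
peaks overlapping peaks from >= k-1 other replicates, then merge) is available
via ``method="peak"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from chipcross.intervals import GenomicInterval, IntervalSet, merge

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel", "AnnotatedPeak", "consensus_peaks", "annotate_region",
    "assign_to_genes", "read_gene_models", "bound_gene_set",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS and (optionally) its body interval."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    body_start: int | None = None
    body_end: int | None = None

    def body(self) -> GenomicInterval | None:
        if self.body_start is None or self.body_end is None:
            return None
        return GenomicInterval(self.chrom, self.body_start, self.body_end,
                               name=self.gene_id)


@dataclass
class AnnotatedPeak:
    interval: GenomicInterval
    region_class: str  # promoter | intronic/genic | intergenic
    gene_ids: tuple[str, ...] = ()
    support: int = 1


def consensus_peaks(
    replicates: Sequence[IntervalSet],
    min_support: int,
    method: str = "base",
) -> IntervalSet:
    """Regions supported by >= ``min_support`` of the replicate peak sets.

    ``method="base"`` (default) emits maximal runs of per-base replicate
    support >= min_support, one interval per run, with the maximum support
    reached inside the run stored in ``score``.  ``method="peak"`` keeps any
    replicate peak overlapping peaks from >= min_support-1 other replicates
    and merges the survivors.

    ``min_support`` larger than the number of replicates yields an empty set
    with a logged warning (not an error).
    """
    if not replicates:
        raise ValueError("need at least one replicate set")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if min_support > len(replicates):
        logger.warning(
            "min_support=%d exceeds the %d replicates; consensus is empty",
            min_support, len(replicates),
        )
        return IntervalSet(label="consensus")
    if method == "base":
        return _consensus_base(replicates, min_support)
    if method == "peak":
        return _consensus_peak_level(replicates, min_support)
    raise ValueError(f"unknown method {method!r}; expected 'base' or 'peak'")


def _consensus_base(replicates: Sequence[IntervalSet], k: int) -> IntervalSet:
    # each replicate contributes at most +1 per base: merge within replicate
    merged_reps = [merge(r) for r in replicates]
    chroms = sorted({c for r in merged_reps for c in r.chromosomes})
    out: list[GenomicInterval] = []
    for chrom in chroms:
        events: list[tuple[int, int]] = []
        for rep in merged_reps:
            for iv in rep.per_chrom(chrom):
                events.append((iv.start, +1))
                events.append((iv.end, -1))
        events.sort()
        depth = 0
        run_start = None
        run_max = 0
        i = 0
        while i < len(events):
            pos = events[i][0]
            while i < len(events) and events[i][0] == pos:
                depth += events[i][1]
                i += 1
            if depth >= k and run_start is None:
                run_start, run_max = pos, depth
            elif run_start is not None:
                if depth >= k:
                    run_max = max(run_max, depth)
                else:
                    out.append(GenomicInterval(chrom, run_start, pos,
                                               score=float(run_max)))
                    run_start = None
    return IntervalSet(out, label="consensus")


def _consensus_peak_level(replicates: Sequence[IntervalSet], k: int) -> IntervalSet:
    trees: list[dict[str, IntervalTree]] = []
    for rep in replicates:
        per = {c: IntervalTree.from_tuples(
            (iv.start, iv.end) for iv in rep.per_chrom(c))
            for c in rep.chromosomes}
        trees.append(per)
    kept: list[GenomicInterval] = []
    for ri, rep in enumerate(replicates):
        for iv in rep:
            others = sum(
                1 for rj, per in enumerate(trees)
                if rj != ri and per.get(iv.chrom) is not None
                and per[iv.chrom].overlaps(iv.start, iv.end)
            )
            if others >= k - 1:
                kept.append(iv)
    return merge(IntervalSet(kept, label="consensus"))


def annotate_region(
    peaks: IntervalSet,
    genes: Sequence[GeneModel],
    gene_bodies: IntervalSet | None = None,
    promoter_halfwidth: int = 1000,
) -> list[AnnotatedPeak]:
    """Classify each peak as promoter, intronic/genic, or intergenic.

    A peak overlapping ``[TSS - hw, TSS + hw)`` of any gene is a promoter
    peak; otherwise one overlapping a gene body is intronic/genic; otherwise
    intergenic.  Precedence: promoter > genic > intergenic.  The promoter
    window ignores strand ("+/-1 kb of TSS" as a symmetric window).
    """
    if promoter_halfwidth <= 0:
        raise ValueError("promoter_halfwidth must be > 0")
    prom_trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo = max(0, g.tss - promoter_halfwidth)
        hi = g.tss + promoter_halfwidth
        prom_trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)
    body_trees: dict[str, IntervalTree] = {}
    bodies = gene_bodies if gene_bodies is not None else IntervalSet(
        [b for g in genes if (b := g.body()) is not None])
    for iv in bodies:
        body_trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, iv.name)
    out: list[AnnotatedPeak] = []
    for iv in peaks:
        support = int(iv.score) if iv.score is not None else 1
        prom = prom_trees.get(iv.chrom)
        hits = prom.overlap(iv.start, iv.end) if prom is not None else ()
        if hits:
            gene_ids = tuple(sorted({h.data for h in hits if h.data}))
            out.append(AnnotatedPeak(iv, "promoter", gene_ids, support))
            continue
        body = body_trees.get(iv.chrom)
        bhits = body.overlap(iv.start, iv.end) if body is not None else ()
        if bhits:
            gene_ids = tuple(sorted({h.data for h in bhits if h.data}))
            out.append(AnnotatedPeak(iv, "intronic/genic", gene_ids, support))
        else:
            out.append(AnnotatedPeak(iv, "intergenic", (), support))
    return out


def _tss_distance(iv: GenomicInterval, tss: int) -> int:
    """bp distance from a peak to a TSS point; 0 when the TSS is inside."""
    return max(0, iv.start - tss, tss - iv.end + 1)


def assign_to_genes(
    peaks: IntervalSet,
    genes: Sequence[GeneModel],
    max_distance: int = 100_000,
) -> dict[str, tuple[str, ...]]:
    """Map each peak to the gene(s) with the nearest TSS within ``max_distance``.

    Ties (identical bp distance) map to all tied genes.  Returns
    ``{peak id: (gene ids,)}``; peaks with no gene in range are omitted.
    The induced bound-gene set is the union of values
    (see :func:`bound_gene_set`).
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.tss)
    out: dict[str, tuple[str, ...]] = {}
    for iv in peaks:
        cands = by_chrom.get(iv.chrom, [])
        if not cands:
            continue
        best = max_distance + 1
        chosen: list[str] = []
        for g in cands:  # gene lists are small; linear scan is the oracle-safe path
            d = _tss_distance(iv, g.tss)
            if d < best:
                best, chosen = d, [g.gene_id]
            elif d == best:
                chosen.append(g.gene_id)
        if best <= max_distance:
            out[iv.id] = tuple(sorted(set(chosen)))
    return out


def bound_gene_set(assignment: Mapping[str, tuple[str, ...]]) -> set[str]:
    """Union of assigned gene ids over all peaks."""
    return {g for genes in assignment.values() for g in genes}


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a 5-column TSV.

    Columns: gene_id, chrom, tss, strand, body (``start-end`` or ``.``).
    Header lines starting with '#' are skipped.
    """
    genes: list[GeneModel] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"line {lineno}: expected 5 columns")
            gene_id, chrom, tss_s, strand, body = fields[:5]
            body_start = body_end = None
            if body != ".":
                try:
                    lo, hi = body.split("-")
                    body_start, body_end = int(lo), int(hi)
                except ValueError as exc:
                    raise ValueError(
                        f"line {lineno}: body must be 'start-end' or '.'"
                    ) from exc
            genes.append(GeneModel(gene_id, chrom, int(tss_s), strand,
                                   body_start, body_end))
    return genes
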