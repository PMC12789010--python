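"""Accessibility partitioning, contingency statistics, DEG filtering and
direction-by-class crosstabs, and id-set overlap summaries.

Chi-squared tests are Pearson's without continuity correction by default
(Yates available for 2x2 via ``correction=True``).  The differential
expression filter is symmetric: up means fold change > ``min_fold``, down
means fold change < ``1/min_fold``, both at ``padj < max_padj``; a missing
padj is never significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from chipcross.intervals import IntervalSet, merge, _merged_arrays, _count_union_overlaps

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyResult", "SetOverlapSummary", "chi2_table",
    "classify_accessibility", "crosstab_chi2", "deg_filter",
    "direction_by_class", "set_overlap_summary", "protein_enrichment_filter",
]


@dataclass
class ContingencyResult:
    observed: np.ndarray
    statistic: float
    dof: int
    p_value: float

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "dof": self.dof,
            "p_value": self.p_value,
            "observed": self.observed.tolist(),
        }


@dataclass
class SetOverlapSummary:
    """Venn-style overlap of two id sets."""

    n_a: int
    n_b: int
    n_shared: int

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_a, self.n_b):
            raise ValueError("|A ∩ B| cannot exceed min(|A|, |B|)")

    @property
    def pct_a_shared(self) -> float:
        return 100.0 * self.n_shared / self.n_a if self.n_a else 0.0

    @property
    def pct_b_shared(self) -> float:
        return 100.0 * self.n_shared / self.n_b if self.n_b else 0.0

    def as_dict(self) -> dict:
        return {
            "n_a": self.n_a, "n_b": self.n_b, "n_shared": self.n_shared,
            "pct_a_shared": self.pct_a_shared,
            "pct_b_shared": self.pct_b_shared,
        }


def chi2_table(observed: np.ndarray, correction: bool = False) -> ContingencyResult:
    """Pearson chi-squared on an r x c table of non-negative counts."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    total = obs.sum()
    if total == 0:
        raise ValueError("empty table (total = 0)")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ValueError(
            "an expected cell is 0 (a row or column is all zeros); "
            "pool sparse categories before testing"
        )
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=correction)
    return ContingencyResult(obs, float(stat), int(dof), float(p))


def classify_accessibility(
    bound: IntervalSet, atac: IntervalSet, min_bp: int = 1
) -> tuple[dict[str, str], dict[str, float]]:
    """Partition bound sites into accessible vs closed chromatin regions (CCR).

    A bound site overlapping >= ``min_bp`` bases of any ATAC peak is
    ``accessible``; otherwise it is a ``CCR``.  Returns per-site labels keyed
    by site id and summary proportions (percent scale).
    """
    labels: dict[str, str] = {}
    arrays = _merged_arrays(atac) if min_bp == 1 else None
    for chrom in bound.chromosomes:
        ivs = bound.per_chrom(chrom)
        if arrays is not None:
            if chrom in arrays and ivs:
                m_start, m_end = arrays[chrom]
                a_start = np.fromiter((iv.start for iv in ivs), dtype=np.int64)
                a_end = np.fromiter((iv.end for iv in ivs), dtype=np.int64)
                idx = np.searchsorted(m_start, a_end, side="left")
                hit = (idx > 0) & (m_end[np.maximum(idx - 1, 0)] > a_start)
            else:
                hit = np.zeros(len(ivs), dtype=bool)
            for iv, h in zip(ivs, hit):
                labels[iv.id] = "accessible" if h else "CCR"
        else:
            atac_ivs = atac.per_chrom(chrom)
            for iv in ivs:
                acc = any(min(iv.end, o.end) - max(iv.start, o.start) >= min_bp
                          for o in atac_ivs)
                labels[iv.id] = "accessible" if acc else "CCR"
    n = len(labels)
    n_ccr = sum(1 for v in labels.values() if v == "CCR")
    props = {
        "n_sites": n,
        "n_ccr": n_ccr,
        "n_accessible": n - n_ccr,
        "pct_ccr": 100.0 * n_ccr / n if n else 0.0,
        "pct_accessible": 100.0 * (n - n_ccr) / n if n else 0.0,
    }
    return labels, props


def crosstab_chi2(
    row_labels: Sequence, col_labels: Sequence, correction: bool = False
) -> ContingencyResult:
    """Cross-tabulate two categorical labelings of the same items and test.

    Expected counts are E_ij = row_i * col_j / total.  An all-zero expected
    cell raises with advice to pool categories.
    """
    if len(row_labels) != len(col_labels):
        raise ValueError("row and column labelings must have equal length")
    if len(row_labels) == 0:
        raise ValueError("empty labelings")
    tab = pd.crosstab(pd.Series(row_labels, name="row"),
                      pd.Series(col_labels, name="col"))
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need >= 2 categories on each axis")
    return chi2_table(tab.to_numpy(), correction=correction)


def deg_filter(
    table: pd.DataFrame,
    min_fold: float = 1.5,
    max_padj: float = 0.05,
) -> pd.DataFrame:
    """Classify each gene as up, down, or ns by fold change and adjusted p.

    ``table`` needs columns gene, log2fc, padj.  up: 2**log2fc > min_fold and
    padj < max_padj; down: 2**log2fc < 1/min_fold and padj < max_padj;
    otherwise (including missing padj) ns.  Returns a copy with a
    ``direction`` column.
    """
    if not (min_fold > 1):
        raise ValueError("min_fold must be > 1")
    if not (0 < max_padj <= 1):
        raise ValueError("max_padj must be in (0, 1]")
    required = {"gene", "log2fc", "padj"}
    if not required.issubset(table.columns):
        raise ValueError(f"DEG table must have columns {sorted(required)}")
    if table["gene"].duplicated().any():
        raise ValueError("gene ids must be unique")
    out = table.copy()
    fold = np.power(2.0, out["log2fc"].astype(float))
    sig = out["padj"].notna() & (out["padj"].astype(float) < max_padj)
    direction = np.where(sig & (fold > min_fold), "up",
                         np.where(sig & (fold < 1.0 / min_fold), "down", "ns"))
    out["direction"] = direction
    return out


def direction_by_class(
    site_classes: Mapping[str, str],
    deg: pd.DataFrame,
    min_fold: float = 1.5,
    max_padj: float = 0.05,
) -> tuple[pd.DataFrame, ContingencyResult]:
    """Crosstab DEG direction against a per-gene site classification.

    ``site_classes`` maps gene id -> class (e.g. "PRDM1_only" vs
    "PRDM1+AP1").  Genes absent from the DEG table count as ns (logged).
    Returns a per-class counts/percentages table and the chi-squared result on
    the class x {up, down} table (ns excluded from the test, as the comparison
    is between significant directions).  Empty classes are excluded with a
    warning.
    """
    ddf = deg_filter(deg, min_fold=min_fold, max_padj=max_padj)
    dir_by_gene = dict(zip(ddf["gene"], ddf["direction"]))
    missing = [g for g in site_classes if g not in dir_by_gene]
    if missing:
        logger.warning("%d classified genes absent from the DEG table; "
                       "counted as ns", len(missing))
    rows = []
    classes = sorted(set(site_classes.values()))
    for cls in classes:
        genes = [g for g, c in site_classes.items() if c == cls]
        if not genes:
            logger.warning("class %s is empty; excluded from the test", cls)
            continue
        dirs = [dir_by_gene.get(g, "ns") for g in genes]
        n = len(dirs)
        n_up = dirs.count("up")
        n_down = dirs.count("down")
        rows.append({
            "class": cls, "n": n, "n_up": n_up, "n_down": n_down,
            "n_ns": n - n_up - n_down,
            "pct_up": 100.0 * n_up / n,
            "pct_down": 100.0 * n_down / n,
        })
    table = pd.DataFrame(rows)
    test_tab = table[["n_up", "n_down"]].to_numpy()
    keep = test_tab.sum(axis=1) > 0
    if keep.sum() < 2:
        raise ValueError("need >= 2 classes with significant genes to test")
    result = chi2_table(test_tab[keep])
    return table, result


def _normalize_ids(ids: Iterable[str]) -> set[str]:
    return {str(i).strip().lower() for i in ids}


def set_overlap_summary(a: Iterable[str], b: Iterable[str]) -> SetOverlapSummary:
    """Venn-style cardinalities of two id sets (whitespace/case normalized)."""
    sa, sb = _normalize_ids(a), _normalize_ids(b)
    return SetOverlapSummary(len(sa), len(sb), len(sa & sb))


def protein_enrichment_filter(
    counts: pd.DataFrame,
    min_ratio: float = 2.0,
    pseudocount: float = 0.5,
) -> set[str]:
    """Proteins whose normalized peptide count is more than ``min_ratio``-fold
    higher in the tagged sample than in the control (strict inequality).

    ``counts`` needs columns protein, count_tagged, count_control.  The
    pseudocount defines behavior at zero controls; pass 0 to disable.
    """
    required = {"protein", "count_tagged", "count_control"}
    if not required.issubset(counts.columns):
        raise ValueError(f"need columns {sorted(required)}")
    tagged = counts["count_tagged"].astype(float)
    control = counts["count_control"].astype(float)
    if (tagged < 0).any() or (control < 0).any():
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (tagged + pseudocount) / (control + pseudocount)
    return set(counts.loc[ratio > min_ratio, "protein"])
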