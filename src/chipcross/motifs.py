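"""PWM scanning inside container intervals, two-motif co-occurrence, and
motif/footprint spacing statistics.

Scores are log-odds in bits: ``log2(prod p_b / prod q_b)`` against a
background ``q`` (default uniform 0.25).  Count matrices get a pseudocount
(default 0.01 per cell) on construction so every probability is positive.

"Distance between motifs" is the per-container minimum center-to-center
distance by default (robust to motif width); an edge-to-edge gap convention
is available via ``convention="edge"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from chipcross.intervals import GenomicInterval, IntervalSet

__all__ = [
    "PWM", "MotifHit", "CooccurrenceTable", "SpacingDistribution",
    "scan_pwm", "classify_cooccurrence", "compare_cooccurrence",
    "pair_distance_distribution", "ks_two_sample",
    "read_jaspar", "read_meme",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over {A, C, G, T}.

    ``probs`` has shape (width, 4); each row sums to 1 after the pseudocount.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 4:
            raise ValueError("probs must be (width >= 4, 4)")
        if not np.all(p > 0):
            raise ValueError("all probabilities must be > 0 after pseudocount")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("rows of probs must sum to 1")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "background",
                           np.asarray(self.background, dtype=float))

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        pseudocount: float = 0.01,
    ) -> "PWM":
        """Build from a (width, 4) count matrix, adding the pseudocount."""
        c = np.asarray(counts, dtype=float) + pseudocount
        probs = c / c.sum(axis=1, keepdims=True)
        return cls(motif_id, probs, np.asarray(background, float), pseudocount)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 4) matrix of log2(p/q) scores."""
        return np.log2(self.probs / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def score(self, seq: str) -> float:
        """Log-odds (bits) of one width-length sequence; -inf on non-ACGT."""
        if len(seq) != self.width:
            raise ValueError("sequence length must equal motif width")
        lo = self.log_odds
        total = 0.0
        for i, base in enumerate(seq.upper()):
            j = _BASE_INDEX.get(base)
            if j is None:
                return float("-inf")
            total += lo[i, j]
        return total


@dataclass(frozen=True)
class MotifHit:
    """A scored PWM (or footprint) occurrence inside a container interval."""

    interval: GenomicInterval
    motif_id: str
    score: float
    strand: str
    container_id: str


@dataclass
class CooccurrenceTable:
    """Per-container A/B presence counts with derived percentages."""

    n_a_only: int
    n_b_only: int
    n_both: int
    n_neither: int
    label_a: str = "A"
    label_b: str = "B"

    @property
    def total(self) -> int:
        return self.n_a_only + self.n_b_only + self.n_both + self.n_neither

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_a_only, self.n_b_only, self.n_both, self.n_neither)

    @property
    def percentages(self) -> tuple[float, float, float, float]:
        if self.total == 0:
            raise ValueError("empty table has no percentages")
        return tuple(100.0 * c / self.total for c in self.counts)

    def as_dict(self) -> dict[str, float]:
        pct = self.percentages
        keys = ("a_only", "b_only", "both", "neither")
        d: dict[str, float] = {}
        for k, c, p in zip(keys, self.counts, pct):
            d[f"n_{k}"] = c
            d[f"pct_{k}"] = p
        d["total"] = self.total
        return d


@dataclass
class SpacingDistribution:
    """Per-container nearest A-B pair distances (bp, non-negative)."""

    distances: list[int]
    bin_width: int = 5

    @property
    def median(self) -> float:
        if not self.distances:
            raise ValueError("empty distribution")
        return float(np.median(self.distances))

    @property
    def mode_bin(self) -> tuple[int, int]:
        """Most populated ``bin_width``-bp bin, as a half-open [lo, hi) range.

        The lowest bin wins ties.
        """
        if not self.distances:
            raise ValueError("empty distribution")
        arr = np.asarray(self.distances)
        bins = arr // self.bin_width
        counts = np.bincount(bins)
        lo = int(counts.argmax()) * self.bin_width
        return (lo, lo + self.bin_width)

    def __len__(self) -> int:
        return len(self.distances)


# ---------------------------------------------------------------------------
# Scanning


def _encode(seq: str) -> np.ndarray:
    """Map ACGT (case-insensitive) to 0..3; anything else to 4."""
    table = np.full(256, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_encoded(codes: np.ndarray, lo_matrix: np.ndarray) -> np.ndarray:
    """Score every window of an encoded sequence; NaN where non-ACGT occurs."""
    w = lo_matrix.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    padded = np.vstack([lo_matrix.T, np.full((1, w), np.nan)])  # row 4: non-ACGT
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return padded[windows, np.arange(w)].sum(axis=1)


def scan_pwm(
    containers: IntervalSet,
    sequences: Mapping[str, str] | "object",
    pwm: PWM,
    threshold: float,
) -> list[MotifHit]:
    """All positions on both strands within each container scoring >= threshold.

    ``sequences`` is any mapping of chromosome name to sequence string — a
    plain dict or a :class:`pyfaidx.Fasta` (records are coerced with
    ``str()``).  Reverse-strand hits are reported on forward coordinates.
    Positions containing non-ACGT bases are skipped.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    lo = pwm.log_odds
    lo_rc = lo[::-1, [_COMPLEMENT[i] for i in range(4)]]
    hits: list[MotifHit] = []
    for container in containers:
        try:
            record = sequences[container.chrom]
        except KeyError as exc:
            raise KeyError(
                f"no sequence for chromosome {container.chrom!r} "
                f"(container {container.id})"
            ) from exc
        record_len = len(record)
        if container.end > record_len:
            raise ValueError(
                f"container {container.id} exceeds sequence bounds "
                f"({container.end} > {record_len})"
            )
        seq = str(record[container.start:container.end])
        codes = _encode(seq)
        for strand, matrix in (("+", lo), ("-", lo_rc)):
            scores = _scan_encoded(codes, matrix)
            idx = np.flatnonzero(~np.isnan(scores) & (scores >= threshold))
            for off in idx:
                start = container.start + int(off)
                hits.append(MotifHit(
                    GenomicInterval(container.chrom, start, start + pwm.width,
                                    name=pwm.motif_id),
                    pwm.motif_id, float(scores[off]), strand, container.id,
                ))
    return hits


# ---------------------------------------------------------------------------
# Co-occurrence and spacing


def _hits_by_container(
    containers: IntervalSet, hits: Iterable[MotifHit], which: str
) -> dict[str, list[MotifHit]]:
    known = {iv.id for iv in containers}
    by: dict[str, list[MotifHit]] = {}
    for h in hits:
        if h.container_id not in known:
            raise ValueError(
                f"{which} hit references unknown container {h.container_id!r}"
            )
        by.setdefault(h.container_id, []).append(h)
    return by


def classify_cooccurrence(
    containers: IntervalSet,
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    label_a: str = "A",
    label_b: str = "B",
) -> CooccurrenceTable:
    """Label each container by presence of >= 1 A hit and >= 1 B hit.

    Counts are invariant to hit order and to duplicate hits within a
    container.  A hit referencing a container not in ``containers`` is an
    error.
    """
    a_by = _hits_by_container(containers, hits_a, label_a)
    b_by = _hits_by_container(containers, hits_b, label_b)
    n = {"a": 0, "b": 0, "both": 0, "neither": 0}
    for iv in containers:
        has_a, has_b = iv.id in a_by, iv.id in b_by
        if has_a and has_b:
            n["both"] += 1
        elif has_a:
            n["a"] += 1
        elif has_b:
            n["b"] += 1
        else:
            n["neither"] += 1
    return CooccurrenceTable(n["a"], n["b"], n["both"], n["neither"],
                             label_a, label_b)


def compare_cooccurrence(table_x: CooccurrenceTable, table_y: CooccurrenceTable):
    """Pearson chi-squared on the 2 (condition) x 4 (class) count table."""
    from chipcross.stats import chi2_table  # local import avoids a cycle

    if table_x.total == 0 or table_y.total == 0:
        raise ValueError("both tables must be non-degenerate (total > 0)")
    obs = np.array([table_x.counts, table_y.counts], dtype=float)
    return chi2_table(obs)


def pair_distance_distribution(
    containers: IntervalSet,
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    convention: str = "center",
    bin_width: int = 5,
) -> SpacingDistribution:
    """Per-container nearest A-B pair distance.

    ``center``: |center_A - center_B| with centers ``floor((start+end)/2)``.
    ``edge``: gap between closest edges, clipped at 0 for overlapping hits.
    Containers lacking either motif contribute nothing.
    """
    if convention not in ("center", "edge"):
        raise ValueError("convention must be 'center' or 'edge'")
    a_by = _hits_by_container(containers, hits_a, "A")
    b_by = _hits_by_container(containers, hits_b, "B")
    distances: list[int] = []
    for iv in containers:
        av, bv = a_by.get(iv.id), b_by.get(iv.id)
        if not av or not bv:
            continue
        best: int | None = None
        for ha in av:
            for hb in bv:
                if convention == "center":
                    d = abs(ha.interval.center - hb.interval.center)
                else:
                    d = max(0,
                            max(ha.interval.start, hb.interval.start)
                            - min(ha.interval.end, hb.interval.end))
                best = d if best is None else min(best, d)
        distances.append(int(best))
    return SpacingDistribution(distances, bin_width=bin_width)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum of |ECDF_x - ECDF_y| over all observed points (ties
    handled by evaluating both ECDFs at every pooled point).  The two-sided
    p-value uses the exact distribution when the effective sample size
    ``n_eff = |x||y|/(|x|+|y|)`` is below 35 and the asymptotic Kolmogorov
    distribution otherwise.
    """
    xa = np.sort(np.asarray(x, dtype=float))
    ya = np.sort(np.asarray(y, dtype=float))
    n, m = len(xa), len(ya)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xa, ya])
    cdf_x = np.searchsorted(xa, pooled, side="right") / n
    cdf_y = np.searchsorted(ya, pooled, side="right") / m
    d = float(np.abs(cdf_x - cdf_y).max())
    n_eff = n * m / (n + m)
    if n_eff < 35:
        p = float(sps.ks_2samp(xa, ya, method="exact").pvalue)
    else:
        p = float(sps.kstwobign.sf(math.sqrt(n_eff) * d))
    return d, min(1.0, p)


# ---------------------------------------------------------------------------
# PWM file formats


def read_jaspar(path: str | Path, pseudocount: float = 0.01,
                background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                ) -> list[PWM]:
    """Read JASPAR raw-count PFMs (``>id name`` header, 4 rows A/C/G/T).

    Accepts both the bracketed dialect (``A  [ 3 5 ... ]``) and bare
    whitespace-separated rows.
    """
    pwms: list[PWM] = []
    motif_id = None
    rows: dict[str, list[float]] = {}
    order = "ACGT"

    def flush() -> None:
        if motif_id is None:
            return
        if set(rows) != set(order):
            raise ValueError(f"motif {motif_id}: expected rows A, C, G, T")
        counts = np.array([rows[b] for b in order]).T
        pwms.append(PWM.from_counts(motif_id, counts, background, pseudocount))

    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                rows = {}
            else:
                parts = line.replace("[", " ").replace("]", " ").split()
                base = parts[0].upper()
                if base not in order:
                    raise ValueError(f"unexpected row label {parts[0]!r}")
                rows[base] = [float(v) for v in parts[1:]]
    flush()
    return pwms


def read_meme(path: str | Path, pseudocount: float = 0.01) -> list[PWM]:
    """Read MEME minimal-motif text (letter-probability matrices).

    Background frequencies are taken from the file's ``Background letter
    frequencies`` block when present, else uniform.
    """
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    with Path(path).open() as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            background = np.array([float(vals[vals.index(b) + 1])
                                   for b in "ACGT"])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].lstrip().startswith(
                    "letter-probability"):
                i += 1
            header = lines[i]
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(i + 1, i + 1 + w):
                rows.append([float(v) for v in lines[j].split()])
            probs = np.array(rows)
            # renormalize through the pseudocount so zeros become positive
            probs = probs + pseudocount
            probs /= probs.sum(axis=1, keepdims=True)
            pwms.append(PWM(motif_id, probs, background, pseudocount))
            i += 1 + w
            continue
        i += 1
    return pwms
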