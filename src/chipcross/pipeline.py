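"""Run configuration and the orchestrated full pipeline.

The pipeline chains: consensus peaks -> region annotation -> PWM scanning and
co-occurrence -> spacing (+ KS when two footprint sets are given) ->
permutation overlap test -> accessibility partition and crosstab -> DEG
direction-by-class crosstab -> id-set overlap summaries.  Stages run when
their inputs are present; a stage explicitly requested without its inputs is
a validation error raised before any computation.

The JSON report is schema-versioned and deterministic (sorted keys, no
timestamps): re-running an identical config yields byte-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from chipcross import consensus as cons
from chipcross import motifs as mot
from chipcross import stats as st
from chipcross.intervals import IntervalSet, read_bed, read_chrom_sizes, write_bed
from chipcross.permutation import permutation_overlap_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_STAGES = ("consensus", "annotate", "cooccur", "spacing", "permtest",
           "accessibility", "degcross", "setoverlap")


@dataclass
class RunConfig:
    """Validated inputs and parameters for :func:`run_pipeline`."""

    seed: int
    out_dir: Path
    replicates: list[Path] = field(default_factory=list)
    atac: Path | None = None
    footprints_a: Path | None = None
    footprints_b: Path | None = None
    deg: Path | None = None
    chrom_sizes: Path | None = None
    fasta: Path | None = None
    pwms: Path | None = None
    genes: Path | None = None
    gene_sets: tuple[Path, Path] | None = None
    stages: list[str] | None = None  # None = run whatever inputs allow
    # parameters
    min_support: int = 2
    promoter_halfwidth: int = 1000
    max_gene_distance: int = 100_000
    scan_threshold: float | None = None  # None = consensus score - 1e-6
    min_fold: float = 1.5
    max_padj: float = 0.05
    n_shuffles: int = 1000
    distance_convention: str = "center"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        inputs = raw.get("inputs", {})
        params = raw.get("parameters", {})
        base = Path(path).parent

        def p(key):
            v = inputs.get(key)
            return (base / v) if v else None

        gene_sets = None
        if inputs.get("gene_sets"):
            a, b = inputs["gene_sets"]
            gene_sets = (base / a, base / b)
        return cls(
            seed=raw["seed"],
            out_dir=base / raw.get("out_dir", "chipcross_out"),
            replicates=[base / r for r in inputs.get("replicates", [])],
            atac=p("atac"), footprints_a=p("footprints_a"),
            footprints_b=p("footprints_b"), deg=p("deg"),
            chrom_sizes=p("chrom_sizes"), fasta=p("fasta"),
            pwms=p("pwms"), genes=p("genes"), gene_sets=gene_sets,
            stages=raw.get("stages"),
            **{k: v for k, v in params.items()},
        )

    def validate(self) -> None:
        """Fail-fast validation: declared paths exist, requested stages have
        their inputs, the seed exists when a stochastic stage will run."""
        declared = list(self.replicates) + [
            self.atac, self.footprints_a, self.footprints_b, self.deg,
            self.chrom_sizes, self.fasta, self.pwms, self.genes,
        ] + (list(self.gene_sets) if self.gene_sets else [])
        for path in declared:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"declared input does not exist: {path}")
        requested = self.stages or []
        needs = {
            "consensus": bool(self.replicates),
            "annotate": self.genes is not None,
            "cooccur": (self.fasta is not None
                        or (self.footprints_a and self.footprints_b)),
            "spacing": (self.fasta is not None
                        or (self.footprints_a and self.footprints_b)),
            "permtest": self.atac is not None and self.chrom_sizes is not None,
            "accessibility": self.atac is not None,
            "degcross": self.deg is not None and self.genes is not None,
            "setoverlap": self.gene_sets is not None,
        }
        for stage in requested:
            if stage not in _STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            if not needs[stage]:
                raise ValueError(
                    f"stage {stage!r} requested but its inputs are missing")
        if ("permtest" in requested or (not requested and needs["permtest"])) \
                and self.seed is None:
            raise ValueError("a seed is required when the permutation stage runs")


def _motif_pwms(config: RunConfig) -> tuple[mot.PWM, mot.PWM]:
    if config.pwms is not None:
        loaded = (mot.read_meme(config.pwms)
                  if Path(config.pwms).suffix in (".meme", ".txt")
                  else mot.read_jaspar(config.pwms))
        if len(loaded) < 2:
            raise ValueError("need at least two PWMs for co-occurrence")
        return loaded[0], loaded[1]
    from chipcross.simulate import MOTIF_A, MOTIF_B
    return MOTIF_A, MOTIF_B


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested (or input-available) stages and write a report.

    Returns the report dict; also writes ``report.json`` and per-stage TSV/BED
    files under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    requested = config.stages
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "parameters": {
            "min_support": config.min_support,
            "promoter_halfwidth": config.promoter_halfwidth,
            "max_gene_distance": config.max_gene_distance,
            "min_fold": config.min_fold,
            "max_padj": config.max_padj,
            "n_shuffles": config.n_shuffles,
            "distance_convention": config.distance_convention,
        },
        "stages": {},
    }

    def wanted(stage: str, available: bool) -> bool:
        if requested is not None:
            return stage in requested
        return available

    containers: IntervalSet | None = None
    if wanted("consensus", bool(config.replicates)):
        reps = [read_bed(r) for r in config.replicates]
        containers = cons.consensus_peaks(reps, config.min_support)
        write_bed(containers, out / "consensus.bed")
        report["stages"]["consensus"] = {
            "n_replicates": len(reps),
            "min_support": config.min_support,
            "n_consensus_peaks": len(containers),
            "total_bp": containers.total_bp(),
        }

    genes = cons.read_gene_models(config.genes) if config.genes else None

    if wanted("annotate", genes is not None) and containers is not None:
        annotated = cons.annotate_region(
            containers, genes, promoter_halfwidth=config.promoter_halfwidth)
        counts: dict[str, int] = {}
        for a in annotated:
            counts[a.region_class] = counts.get(a.region_class, 0) + 1
        report["stages"]["annotate"] = {"region_counts": counts}

    hits_a = hits_b = None
    label_a = label_b = None
    if config.footprints_a and config.footprints_b and containers is not None:
        fa = read_bed(config.footprints_a)
        fb = read_bed(config.footprints_b)
        hits_a = _intervals_to_hits(containers, fa, "A")
        hits_b = _intervals_to_hits(containers, fb, "B")
        label_a, label_b = Path(config.footprints_a).stem, \
            Path(config.footprints_b).stem
    elif config.fasta is not None and containers is not None:
        import pyfaidx

        fasta = pyfaidx.Fasta(str(config.fasta))
        pwm_a, pwm_b = _motif_pwms(config)
        thr_a = (config.scan_threshold if config.scan_threshold is not None
                 else pwm_a.max_score - 1e-6)
        thr_b = (config.scan_threshold if config.scan_threshold is not None
                 else pwm_b.max_score - 1e-6)
        hits_a = mot.scan_pwm(containers, fasta, pwm_a, thr_a)
        hits_b = mot.scan_pwm(containers, fasta, pwm_b, thr_b)
        label_a, label_b = pwm_a.motif_id, pwm_b.motif_id

    cooccur_table = None
    if wanted("cooccur", hits_a is not None) and hits_a is not None:
        cooccur_table = mot.classify_cooccurrence(
            containers, hits_a, hits_b, label_a, label_b)
        report["stages"]["cooccur"] = {
            "label_a": label_a, "label_b": label_b,
            **cooccur_table.as_dict(),
        }

    if wanted("spacing", hits_a is not None) and hits_a is not None:
        spacing = mot.pair_distance_distribution(
            containers, hits_a, hits_b, convention=config.distance_convention)
        stage: dict = {"n_pairs": len(spacing)}
        if len(spacing):
            stage["median_bp"] = spacing.median
            stage["mode_bin_bp"] = list(spacing.mode_bin)
            pd.DataFrame({"distance_bp": spacing.distances}).to_csv(
                out / "spacing.tsv", sep="\t", index=False)
        # KS against the spacing of any-vs-any hits when both footprint
        # sets are interval inputs (the two-distribution comparison)
        all_hits = list(hits_a) + list(hits_b)
        any_spacing = mot.pair_distance_distribution(
            containers, all_hits, all_hits,
            convention=config.distance_convention)
        any_nonzero = [d for d in any_spacing.distances if d > 0]
        if len(spacing) and len(any_nonzero):
            d_stat, p = mot.ks_two_sample(spacing.distances, any_nonzero)
            stage["ks_vs_all_pairs"] = {"D": d_stat, "p_value": p}
        report["stages"]["spacing"] = stage

    atac = read_bed(config.atac) if config.atac else None

    if wanted("permtest", atac is not None and config.chrom_sizes is not None) \
            and atac is not None and containers is not None:
        layout = read_chrom_sizes(config.chrom_sizes)
        perm = permutation_overlap_test(
            containers, atac, layout,
            n_shuffles=config.n_shuffles, seed=config.seed)
        report["stages"]["permtest"] = perm.summary()
        pd.DataFrame({"null_overlap": perm.null_counts}).to_csv(
            out / "null_counts.tsv", sep="\t", index=False)

    access_labels = None
    if wanted("accessibility", atac is not None) and atac is not None \
            and containers is not None:
        access_labels, props = st.classify_accessibility(containers, atac)
        stage = dict(props)
        if cooccur_table is not None and hits_a is not None:
            class_by_container = _container_classes(containers, hits_a, hits_b)
            ids = [iv.id for iv in containers]
            try:
                ct = st.crosstab_chi2(
                    [class_by_container[i] for i in ids],
                    [access_labels[i] for i in ids])
                stage["crosstab_by_motif_class"] = ct.as_dict()
            except ValueError as exc:
                stage["crosstab_by_motif_class"] = {"skipped": str(exc)}
        report["stages"]["accessibility"] = stage

    if wanted("degcross", config.deg is not None and genes is not None) \
            and config.deg is not None and genes is not None \
            and containers is not None and hits_a is not None:
        deg = pd.read_csv(config.deg, sep="\t")
        assignment = cons.assign_to_genes(
            containers, genes, max_distance=config.max_gene_distance)
        class_by_container = _container_classes(containers, hits_a, hits_b)
        gene_classes: dict[str, str] = {}
        for peak_id, gene_ids in assignment.items():
            for g in gene_ids:
                prev = gene_classes.get(g)
                cur = class_by_container[peak_id]
                gene_classes[g] = _merge_class(prev, cur)
        table, ct = st.direction_by_class(
            gene_classes, deg,
            min_fold=config.min_fold, max_padj=config.max_padj)
        table.to_csv(out / "deg_by_class.tsv", sep="\t", index=False)
        report["stages"]["degcross"] = {
            "per_class": table.to_dict(orient="records"),
            "chi2": ct.as_dict(),
        }

    if wanted("setoverlap", config.gene_sets is not None) \
            and config.gene_sets is not None:
        sa = {l.strip() for l in Path(config.gene_sets[0]).read_text().split()
              if l.strip()}
        sb = {l.strip() for l in Path(config.gene_sets[1]).read_text().split()
              if l.strip()}
        report["stages"]["setoverlap"] = st.set_overlap_summary(sa, sb).as_dict()

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _intervals_to_hits(containers: IntervalSet, footprints: IntervalSet,
                       motif_id: str) -> list[mot.MotifHit]:
    """Attach footprint intervals to the containers they fall in."""
    hits = []
    for chrom in footprints.chromosomes:
        conts = containers.per_chrom(chrom)
        for fp in footprints.per_chrom(chrom):
            for c in conts:
                if fp.start < c.end and fp.end > c.start:
                    hits.append(mot.MotifHit(fp, motif_id,
                                             fp.score or 0.0, fp.strand, c.id))
    return hits


def _container_classes(containers: IntervalSet, hits_a, hits_b) -> dict[str, str]:
    a_ids = {h.container_id for h in hits_a}
    b_ids = {h.container_id for h in hits_b}
    out = {}
    for iv in containers:
        has_a, has_b = iv.id in a_ids, iv.id in b_ids
        out[iv.id] = ("both" if has_a and has_b else
                      "A_only" if has_a else
                      "B_only" if has_b else "neither")
    return out


def _merge_class(prev: str | None, cur: str) -> str:
    """Gene class = union of its peaks' motif content (multi-peak genes)."""
    if prev is None or prev == cur:
        return cur
    ranks = {"neither": 0, "A_only": 1, "B_only": 1, "both": 2}
    has_a = "A_only" in (prev, cur) or "both" in (prev, cur)
    has_b = "B_only" in (prev, cur) or "both" in (prev, cur)
    if has_a and has_b:
        return "both"
    return prev if ranks[prev] >= ranks[cur] else cur
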