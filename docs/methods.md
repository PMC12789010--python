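# Methods

This note documents the models, conventions and numerical choices behind
`chipcross`, and what the synthetic-data tests do and do not establish about
real data.

## Coordinate and overlap conventions

All intervals are 0-based half-open (`[start, end)`, BED convention).
Book-ended intervals share no base, so they do **not** overlap, but they
**do** fuse under `merge(..., max_gap=0)`. Chromosome names are exact
strings; no `chr`/Ensembl aliasing is attempted. "Overlap" between two
intervals means at least `min_bp` shared bases with `min_bp = 1` by default
(single shared base, the common bedtools reading); the threshold is exposed
because published analyses rarely state it. narrowPeak summit offsets are
converted to absolute 0-based positions on read.

## Consensus peaks

"Present in at least *k* samples" is ambiguous between peak-level and
base-level support. The default is base-level: each replicate is first
self-merged (so one replicate contributes at most +1 per base), per-base
support is computed with an event sweep, and maximal runs with support ≥ *k*
become consensus peaks, carrying the maximum support reached inside the run
as their score. This definition is order-independent and reproducible. The
peak-level alternative (keep any replicate peak overlapping peaks from
≥ *k*−1 other replicates, then merge) is available via `method="peak"`.
`min_support` larger than the number of replicates yields an empty set with a
logged warning rather than an error, because it is a legitimate (if vacuous)
parameter choice in scripted sweeps.

## Annotation and gene assignment

A peak overlapping `[TSS − h, TSS + h)` (default h = 1000 bp, strand-ignored)
of any gene is a promoter peak; otherwise a peak overlapping a gene body is
intronic/genic; otherwise intergenic — precedence promoter > genic >
intergenic, so the three classes partition any peak set. Peak→gene
assignment maps each peak to the gene(s) with the nearest TSS within
`max_distance` (default 100 kb; published pipelines rarely state their rule,
so this is a configurable convention, not an inference). The distance from a
peak to a TSS is 0 when the TSS lies inside the peak and the base gap to the
nearer edge otherwise; exact ties map to all tied genes.

## PWM scanning

Count matrices get a pseudocount of 0.01 per cell on read (JASPAR raw counts
and MEME minimal text are both supported), then rows are normalized.
Scores are log-odds in bits against a background (default uniform 0.25).
Scanning scores every position of both strands inside each container;
reverse-strand hits are reported on forward coordinates; windows containing
non-ACGT bases are skipped. A scan on a sequence and on its reverse
complement yields mirror-image hits with identical scores (property-tested).

## Co-occurrence, spacing, KS

Each container is labeled by presence of ≥1 A hit and ≥1 B hit, giving the
A-only / B-only / both / neither table; counts are invariant to hit order and
duplicates. Condition tables are compared with Pearson chi-squared on the
2×4 table (df = 3).

"Distance between motifs" is not uniquely defined in the field; the default
here is the per-container **minimum center-to-center** distance, centers
computed as `floor((start+end)/2)`, which is robust to motif width. An
edge-to-edge gap convention (clipped at 0 for overlapping hits) is exposed as
`convention="edge"`. No exclusion window is applied near 0. Neither
convention is claimed to match any specific published figure.

The two-sample KS statistic is D = supₜ|F̂ₓ(t) − F̂ᵧ(t)| with the supremum
evaluated at all pooled sample points (tie-safe). The p-value uses the exact
two-sided distribution when the effective size n·m/(n+m) is below 35 and the
asymptotic Kolmogorov distribution above.

## Shuffle null and empirical p

The permutation null re-places each query interval with its length preserved.
Defaults: per-chromosome placement (`keep_chrom=True`, like
`bedtools shuffle -chrom`) because cross-chromosome placement inflates
significance under nonuniform chromosome composition; shuffled intervals may
overlap one another (bedtools default; a no-self-overlap mode exists);
placements intersecting excluded regions are redrawn up to 1000 times before
a hard error naming the interval. Only the query set is shuffled, never the
target; a swap is a caller-side argument change. Empirical significance uses
the add-one rule p = (r+1)/(N+1), which is unbiased and never zero. Sub-seed
for shuffle *i* is `seed + i`, so runs are reproducible and parallelizable by
index. When `min_bp=1`, no exclusions apply and placement is per-chromosome,
the null loop runs on a vectorized array path (uniform draws + searchsorted
against the merged target); it consumes the same random stream as the
object-level shuffle and is tested shuffle-by-shuffle against it.

## Accessibility, DEG filter, crosstabs

A bound site overlapping ≥1 bp of any ATAC peak is "accessible", otherwise a
closed chromatin region (CCR); the two labels partition the sites. The DEG
filter is symmetric: up means 2^log2fc > 1.5, down means 2^log2fc < 1/1.5,
both require padj < 0.05 (strict); a missing padj is never significant.
Chi-squared tests are Pearson's without continuity correction (Yates
available for 2×2); a zero expected cell is an error with advice to pool
categories, not a silent NaN. The direction-by-class crosstab tests the
class × {up, down} table, excluding ns counts, since the comparison of
interest is between significant directions; genes classified by sites but
absent from the DEG table are counted as ns and logged. When one gene has
several bound peaks with different motif content, its class is the union of
its peaks' motif content (a gene with an A-only and a B-only peak is "both");
such merges are deterministic. The proximity-proteomics filter keeps a
protein iff (tagged + c)/(control + c) strictly exceeds the ratio threshold
(default 2.0), with pseudocount c = 0.5 to define behavior at zero controls.

## Synthetic-data generator

The generator emulates the post-peak-calling layer of a two-condition TF
binding study. Defaults are the study conditions: 1000 peaks of 300 bp on a
2 × 1 Mb uniform-base genome; planted motif classes 593 / 97 / 171 / 139
(A-only / B-only / both / neither — the printed class percentages at
n = 1000); A–B center spacing Normal(25, 5) bp, rounded half-away-from-zero
and truncated at the wider motif width so instances never overlap; three
replicates with 80% per-peak detection and boundary jitter sd 10 bp;
class-conditional accessibility (A-only 0.6, B-only 0.9, both 0.75,
neither 0.7 — the A-only class least accessible, as observed for direct
PRDM1-motif binding); class-conditional P(up) (both 0.6 > A-only 0.2, with
B-only 0.4 and neither 0.3) and |log2fc| effect 1.5 for significant genes.
Where the motivating study prints no value, these are one-time choices of
realistic magnitudes, recorded here, and are not tuned.

Design points worth knowing:

- **Placement.** Peaks are laid on an equal-slot grid per chromosome with a
  uniform offset inside each slot — non-overlap is guaranteed without
  rejection loops, at the cost of mild regularity. For permutation-null
  calibration this regularity would distort the null (stratified placement
  has lower overlap variance than iid placement), so a separate generator
  (`simulate_independent_sets`) draws intervals iid uniform — exactly the
  shuffle null's placement model.
- **Counts mode vs fractions mode.** Counts mode plants exact per-class
  cardinalities (worked-example ratios need exact printed counts); fractions
  mode draws each peak's class independently, giving binomial noise for
  calibration tests. The truth table records the mode.
- **Motif planting.** The two built-in PWMs are a PRDM1-like 12-mer
  (consensus GAAAGTGAAAGT) and a RUNX-like 10-mer (TGTGGTTTGT), built from
  count matrices with a dominant count of 97 per position. Instances are
  embedded into the FASTA as exact consensus strings (overwriting background
  bases, forward strand), so a scan at threshold = consensus score − ε
  rediscovers every planted instance; on a uniform background the expected
  number of chance 12-mer/10-mer exact matches inside 300 kb of containers
  is ≲ 1, so scanner-based class tables may differ from planted tables by at
  most a container or two.
- **ATAC peaks** for accessible sites are centered on the bound site and
  truncated at its boundaries, so an ATAC peak never leaks into a
  neighboring site and planted accessibility labels are recovered exactly.
- **Determinism.** Every generator is a pure function of the configuration;
  the seed is mandatory. Stage sub-seeds are seed + {0,1,2,3,4} for genome,
  peaks, replicates, accessibility, DEG. All jitter rounding is
  half-away-from-zero for cross-language reproducibility.

What passing on this generator does **not** show: robustness to peak-width
and fragment-length distributions of real ChIP/ATAC data, non-uniform
(GC-biased, repeat-masked) genomic backgrounds, degenerate real motifs far
from their consensus, correlated replicate failures, or p-value behavior of
DESeq2-style shrunken fold changes. DEG tables, footprint calls and
differential-accessibility regions are consumed as inputs in real use; their
upstream estimation is out of scope.

## Problem sizes and numerical checks

The test suite runs oracle-equivalence checks (quadratic pairwise overlap,
per-base union/support membership, exhaustive rescans, ECDF suprema) on
≥ 200 random small instances per operation; permutation calibration uses 200
independent seeds × 200 shuffles with 200 query intervals on a 2 × 1 Mb
genome (fraction of p ≤ 0.05 checked against [0.02, 0.10], the 3·SE band
around 0.05 at 200 draws); planted-containment power uses 500 query
intervals with 50% containment; parameter-recovery suites use 100 seeds at
500 sites/class (accessibility) and 400 genes/class (expression), asserting
recovery within 3 binomial standard errors and chi-squared p < 0.01 in ≥ 95
of 100 seeds. These sizes were chosen to make the statistical assertions
sharp (3·SE bands, ≥ 95/100 power) while keeping the whole suite fast on one
CPU. The acceptance script regenerates each printed-ratio fixture at its
published cardinality (up to 4,997 sites).

## Known limitations

- The base-resolution consensus definition can split one fuzzy replicate
  peak into several consensus runs when support dips locally; the peak-level
  method avoids this at the cost of order-of-definition asymmetries.
- `overlap_count` with `min_bp > 1` is exact but falls back to a per-interval
  scan (O(|A|·|B|) worst case on one chromosome).
- The PWM scanner has no dinucleotide background model and reports no
  E-values; it is a locator for known motifs, not a discovery tool.
- The shuffle null models placement only; it is not GC- or gap-matched.
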