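# chipcross

Integrative ChIP-seq / ATAC-seq / RNA-seq interval analysis for
transcription-factor binding studies, built around the question of how a
repressive TF (the motivating case: PRDM1/Blimp-1 in human NK cells) divides
its genome-wide binding sites by motif content, chromatin accessibility, and
downstream transcriptional effect.

It is aimed at computational biologists who already have peak calls,
footprint calls and differential-expression tables, and who need the
*integration* layer to be reproducible and testable:

- **Consensus peaks** across replicates — maximal genomic runs where at least
  *k* of *n* replicate peak sets have coverage (a peak-level variant is also
  available), plus promoter / intronic-genic / intergenic annotation against
  a TSS table (promoter = ±1 kb of TSS by default) and nearest-TSS gene
  assignment.
- **Motif scanning and co-occurrence** — PWM log-odds scanning
  (score = log₂ ∏pᵦ/∏qᵦ, both strands) inside container intervals, per-peak
  two-motif classification into A-only / B-only / both / neither, and the
  per-peak nearest-pair spacing distribution with a two-sample
  Kolmogorov–Smirnov test (D = supₜ|F̂ₓ(t) − F̂ᵧ(t)|).
- **Shuffle-null overlap significance** — genome-aware random re-placement of
  the query set (lengths preserved, per-chromosome by default, excluded
  regions respected) and the empirical p-value p = (r+1)/(N+1) for the
  observed overlap count against N shuffles.
- **Accessibility and expression crosstabs** — accessible-vs-CCR (closed
  chromatin region) partitioning of bound sites by ATAC overlap, Pearson
  chi-squared contingency tests, the differential-expression filter
  (fold change > 1.5, padj < 0.05, symmetric in both directions),
  direction-by-class crosstabs, Venn-style id-set summaries, and the
  >2-fold proximity-proteomics enrichment filter.
- **Synthetic data with planted truth** — deterministic generators for every
  input above (genome FASTA, peaks with planted motif classes and spacings,
  noisy replicates, class-conditional accessibility and expression, id-set
  pairs with exact overlaps), so each stage's recovery can be asserted
  without any external download.

## Worked example

```python
from chipcross.simulate import SimulationConfig, write_simulation
from chipcross.pipeline import RunConfig, run_pipeline

# synthetic study: 1000 bound peaks, motif classes 593/97/171/139,
# mean motif spacing 25 bp, 3 replicates at 80% detection
write_simulation(SimulationConfig(seed=7), "sim")
```

then run the chained pipeline (also available as `chipcross run --config`):

```python
config = RunConfig(
    seed=7, out_dir="out",
    replicates=["sim/rep1.bed", "sim/rep2.bed", "sim/rep3.bed"],
    atac="sim/atac.bed", deg="sim/deg.tsv", genes="sim/genes.tsv",
    chrom_sizes="sim/genome.chrom.sizes", fasta="sim/genome.fa",
    n_shuffles=100,
)
report = run_pipeline(config)
```

Key numbers from the resulting `report.json` (seed 7):

```
consensus:      884 consensus peaks from 1000 planted (3 reps, support >= 2)
cooccur:        59.2% A-only, 9.8% B-only, 17.6% both, 13.3% neither
spacing:        median 24 bp, modal 5-bp bin [20, 25)
permtest:       observed overlap 600, null mean 176.8, p = 1/101
accessibility:  32.1% CCR; chi-squared across motif classes p = 1.8e-05
degcross:       64.1% of doubly-bound genes up vs 22.2% of A-only, p = 8.9e-18
```

Reading: ~88% of planted peaks survive the replicate-support filter at the
configured 80% detection rate; the planted class fractions, 25 bp spacing,
class-dependent accessibility and the higher up-regulated fraction among
doubly-bound genes are all recovered, and the consensus/ATAC overlap is far
beyond the shuffle null (p at the add-one floor for 100 shuffles).

A console script exposes each stage directly:

```bash
chipcross simulate --seed 7 --out sim
chipcross consensus sim/rep*.bed --min-support 2 --out consensus.bed
chipcross permtest --query consensus.bed --target sim/atac.bed \
    --genome sim/genome.chrom.sizes --n 1000 --seed 7
```

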