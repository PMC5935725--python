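# Methods

## Signal model and normalization chain

A ChIP sample is reduced to a binned coverage track: the value of bin *b* is
the number of read bases overlapping *b* divided by the bin size, so
`bin_size=1` reproduces per-nucleotide coverage and aggregating the
per-nucleotide track to size *k* equals computing at *k* directly. The
default bin size is 200 bp, a common choice for broad histone marks; profiles
and gene-body means interpolate bin edges by overlap, so results change only
mildly with bin size.

The chain then runs in a fixed order — scale, subtract, calibrate:

1. **Unit-mean scaling.** Each track is multiplied by
   (number of genome bins / total signal), making its genome-wide mean
   intensity exactly 1. This removes sequencing-depth differences but also
   any true global difference between samples.
2. **Poisson input subtraction.** The input control (unit-mean scaled) is
   rescaled to the ChIP library's depth *d* (mean mapped reads per bin),
   giving a background rate λ = input × *d* per bin. The subtracted
   background is the upper (1 − p) Poisson quantile
   u(λ) = min{k : CDF(k; λ) ≥ 1 − p}, converted back to intensity units
   (u/d), with the result floored at 0. Default p = 0.001. The quantile
   rule, rather than subtracting λ itself, is deliberately conservative: a
   bin survives only if its ChIP signal exceeds what input noise alone would
   produce with probability 1 − p. A consequence worth knowing: at lower
   depth the quantile overhead is relatively larger, so shallower libraries
   lose a larger fraction of diffuse signal; comparisons of *total* signal
   between samples should therefore be read from the calibrated means, not
   from post-subtraction totals. An all-zero input is treated as λ = 0
   everywhere (no subtraction) with a warning.
3. **Global calibration.** Each track is multiplied by its global
   modification level — an external per-sample measurement (in practice a
   quantified Western blot) expressed relative to a reference sample whose
   level is 1. After this step the genome-wide mean of a track equals its
   global level, so between-sample ratios are quantitative. The calibration
   table requires at least one level-1 reference per mark; more than one is
   legal because a sample whose global level did not change relative to the
   reference is itself at 1.

Scaling and calibration are monotone (bin rankings are preserved); the order
scale → subtract → calibrate is fixed, since subtraction is not commutative
with the multiplicative steps.

## Summaries

*Gene-body means* average the calibrated track over [start, end) with
edge bins weighted by overlap (equal to the per-base mean).

*TSS metagene profiles* sample the track at 2·window/step positions whose
offsets are profile-bin centers ±(k + ½)·step, symmetric about 0; rows for
minus-strand genes are flipped so positive offsets are always downstream of
transcription. The TSS of a minus-strand gene is end − 1 in 0-based
half-open coordinates. Genes whose window crosses a chromosome end are
dropped and counted rather than zero-padded, avoiding edge artifacts.
Defaults: window ±2,500 bp, step 50 bp. Profiles use all annotated genes
unless a gene-group table restricts them.

*Mark ratio.* The H3K36me2/H3K27me3 curve is the pointwise ratio
me2/(me3 + ε) of two group mean curves on the same offset axis, with
ε = 0.01 (1% of a typical calibrated level, since calibrated tracks have
genome mean of order 1); ε is disclosed in the run manifest.

## Expression classification

RPKM = counts / (exonic length / 10³) / (library size / 10⁶). Calls use a
pseudocount c = 0.5 RPKM so zero-baseline genes are callable, and an
inclusive threshold (ratio ≥ T counts as up) so the boundary is reproducible;
for continuous data the boundary has measure zero. T defaults to 2
(twofold). "Failed to be induced" is operationalized as: the mutant-course
fold change (mutant D2 + c)/(mutant D0 + c) is below the same T used for the
control call. An alternative reading — mutant endpoint below a fraction of
the control endpoint — is available as `rule="level"`; the fold-based rule is
the default because it applies the identical criterion to both genotypes.

Selectivity rankings order genes by log2((A + c)/(B + c)) descending with
ties broken by gene id, so output order is strict and deterministic; the top
N per direction are flagged, and a gene already A-selected is never also
B-selected when 2N exceeds the gene count. Log base 2 is used for all fold
changes. Percentages in summaries are |set|/total to one decimal.

Replicate columns, when present, can be averaged into a single RPKM column
before classification; the study design this package targets is unreplicated
per timepoint, so this is an extension, not a default.

## Synthetic data: what it emulates, and what it does not

The generator plants every quantity the pipeline is supposed to recover:

- **Genome/annotation**: equal-length chromosomes (default 2 × 1 Mb) with
  non-overlapping genes (3–8 kb) on alternating strands, exonic length
  40–90% of the body.
- **ChIP reads**: per-bin Poisson counts at background rate 5 reads/bin,
  times a fold for enrichment domains (default 4× over 10% of gene bodies),
  times an optional TSS-proximal factor, times the planted global depletion
  (default 0.3) for the mutant's depleted mark only. Reads are single-end,
  fixed 50 bp, uniformly placed within their bin — the simplest model
  consistent with the Poisson-subtraction assumption. The realized
  read-total ratio between conditions converges to the planted factor as the
  bin count grows.
- **Input**: the same Poisson background with no enrichment, shared across
  conditions.
- **Calibration table**: reports each sample's true global factor — i.e. the
  synthetic Western blot measures without error.
- **Expression**: four samples (WT/MUT × D0/D2); baseline 1–100 RPKM
  (log-uniform), induced genes rise 4-fold in WT, sensitive genes rise only
  1-fold in the mutant; counts are rounded from expected RPKM at a 2 × 10⁶
  library. Measurement noise is multiplicative log-normal with σ = 0.1 by
  default; σ = 0 is the noiseless mode for exact-recovery tests. Planted set
  sizes are round(fraction × n) at each level.

One integer seed drives everything through label-keyed substreams
(`(seed, crc32(label))`), so adding a sample never perturbs another sample's
draws and identical spec + seed reproduce outputs byte-for-byte.

Deliberately absent from the simulation: fragment-size distributions, GC and
mappability bias, duplicate reads, paired ends, biological replicates, and
overdispersion beyond Poisson/log-normal. Passing tests therefore show that
the *procedures* are correct and self-consistent, not that they are robust to
every artifact of real sequencing data; in particular the calibration step's
accuracy on real data is bounded by the accuracy of the Western-blot
quantification, which the synthetic table idealizes as exact.

## Numerical and design choices

- Internal coordinates are uniformly 0-based half-open; GTF is converted on
  input, bedGraph/BED pass through.
- bedGraph values carry 6 significant digits; zero runs are written
  explicitly so a re-read track has an unambiguous genome-wide mean;
  adjacent equal-value bins are merged.
- The Poisson quantile uses `scipy.stats.poisson.ppf`; the test suite checks
  it bin-for-bin against direct CDF enumeration.
- Unit-mean scaling of an all-zero track and percentages over a zero total
  are errors, not NaNs.
- Config files are strictly validated: unknown keys are rejected so a typo
  in a threshold cannot silently revert a default. Every numeric factor
  applied to data (scaling factor, calibration level, p, dropped-gene
  counts) is recorded in the run manifest, and reruns with identical config
  and inputs are hash-identical (figures excluded).
- Problem sizes in tests and the demo (1–2 Mb genomes, 10⁴ bins, 100–300
  genes) are chosen so the full suite runs in seconds while keeping ≥10⁴
  Poisson draws behind every stochastic assertion.

## Known limitations

- The Poisson subtraction rule is this package's own concrete choice of
  "subtract input under a Poisson model"; other published variants subtract
  the rate itself or use local windows.
- Gene-body and profile statistics assume one transcript per gene; exonic
  length is an annotation input, not computed from transcript models.
- The global calibration factor applies uniformly; locus-dependent
  efficiency differences between samples are not modeled.
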