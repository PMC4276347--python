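# Methods

## Coordinate and interval conventions

All coordinates are 0-based half-open. GTF input (1-based closed) is
converted on read; BED passes through. The TSS of a + strand gene is its
span start; of a − strand gene, `span_end − 1`. Promoters are TSS ± 200 bp
on both strands. The upstream control window is 400 bp centred 2 kb
upstream of the TSS in transcript orientation (on the − strand this is
rightward in genome coordinates); "centred" is our choice — only the
window's width and distance are fixed by the design. Intervals clipped at
chromosome boundaries are kept and flagged rather than dropped, so gene
sets remain complete partitions. Where a gene has several annotated TSSs,
each gets its own promoter and the gene-level score is the
maximum-scoring promoter; OR-combining activity across promoters gives
identical booleans but no longer yields one score per gene.

## cRPKM scoring and the activity call

A tag contributes to every interval it overlaps by ≥ 1 bp (promoters of
distinct genes may abut, so double counting is allowed). Per mark,
`RPKM = count / (interval_kb × library_millions)`, each mark normalised by
its own library; the cumulative score is the sum over H3K4me3 and H3ac.
Library size is the total tag count of the supplied library, with no
duplicate removal: amplicon artifacts are kept and handled by the
single-mark rule instead.

The activity call is `cRPKM > threshold`, strict, with threshold default
8 (score units). The single-mark rule sets a promoter inactive when one
mark's RPKM is below `single_mark_epsilon` (default 0.5 RPKM) while the
total clears the threshold; `amplicon_suspect` is additionally raised when
at least `amplicon_fraction` (default 0.75) of the dominant mark's
overlapping tags share one identical 5′ position. The phenomenon (a
single spurious amplicon carrying a promoter over the cutoff) dictates the
rule's shape but not its constants, so both are config-exposed.

The antimode estimator fits a Gaussian KDE (Scott bandwidth) to
`log10(cRPKM + 0.1)` — the offset admits zero scores and is configurable —
on a 512-point grid, takes the two highest local maxima carrying at least
5% of the peak density (tail wiggles are not modes), and returns the
density minimum between them, back-transformed. If fewer than two modes
survive, or the valley is not at least 5% below the lower mode, the result
is an absent value with a diagnostic, never an exception. Interval overlap
counting is backed by pyranges (NCLS); the test suite keeps an independent
quadratic brute-force oracle.

## Expression, protein and stability quantification

GRO-seq RPKM is computed over whole gene spans, strand-matched when both
tags and annotation carry strands (logged either way), or ingested from a
per-gene count table whose header records the library depths. RNA-seq FPKM
is ingested as a per-gene table. Peptide iTRAQ log₂ ratios are collapsed
per gene by the median (mean by config) after dropping peptides not
unambiguously mapped to a single gene; a gene with no usable peptides has
an absent protein value, not zero. All differential quantities are
`log(a/b)` (base 10 or 2, each output column names its base) and are
absent when either side is zero — exclusion, not pseudocounts. Inferred
stability is FPKM/RPKM per state; its cross-state differential equals
log₁₀(FPKM ratio) − log₁₀(RPKM ratio) exactly wherever defined.

## Axis states and the regulatory classifier

Axis states use inclusive fold cutoffs (transcription 2, mRNA 2, protein
1.5). A zero versus a value below the expression floor (default 0.5
RPKM/FPKM) is undefined rather than an infinite fold; a zero against a
clearly expressed value is a real change. The floor exists because the
zero-versus-nonzero case is otherwise ill-posed under exclusion rules.

The 27 combinations are enumerated transcription-major with
up < unchanged < down, ids 1–27. The collapse onto broad groups follows
the verbal definitions: protein unchanged → no-protein-change (9
triples); protein, transcription and mRNA concordant → transcriptional
(2); protein changed with transcription unchanged → post-transcriptional
(6; mRNA moving with the protein ⇒ mRNA-level, else downstream); the 10
remaining discordant triples, and any gene whose protein changed while an
RNA axis is undefined, are undetermined/ambiguous. Because the exact
published collapse table is not available, the mapping ships as data
(`classify.default_mapping()`, overridable from TSV) and the partition
sizes 9/2/6/10 are asserted in tests. Genes with undefined protein state
are excluded from grouping and reported separately.

## Statistics

The rank-sum test uses exact enumeration for untied samples with
n₁ + n₂ ≤ 20 and otherwise the normal approximation with tie and
continuity correction (the method used is recorded); identical constant
samples return p = 1 with a degenerate flag. Quartile strata split at the
empirical 25/50/75 percentiles by stable positional rank, ties broken by
input order. Frequency distributions use left-closed bins of fixed width
aligned to multiples of the width (defaults 0.1 for log-scale expression
ratios, 0.25 for protein log₂ ratios).

Enrichment of an interval set against a reference: base-pair Jaccard
after merging both sets; a projection test comparing the number of query
midpoints inside the merged reference with Binomial(n, reference
coverage / genome size), two-sided by the minlike convention (summing
outcomes no more probable than observed); and a relative-distance test —
each query midpoint's distance to its nearest flanking reference point,
scaled by the flanking gap, is uniform on [0, 0.5] under no association.
Its statistic is the sup distance between the binned empirical CDF
(20 bins) and the uniform CDF, with a Monte-Carlo p-value (default 1,000
seeded uniform resamples; the add-one estimator keeps p in (0, 1]). The
projection test's midpoint convention and the Monte-Carlo null are our
choices; the alternatives (any-overlap; more resamples) are config
switches. Raw p-values are reported without multiple-testing correction.

## The synthetic generator

The generator emulates the statistical structure of the study on a toy
genome and is the ground truth for every recovery test:

* **Genome**: 4 chromosomes, 2 Gb total regardless of gene count, genes on
  random strands with log-normal lengths (median ≈ 2.5 kb) spaced evenly —
  a fixed genome size keeps background tag density per promoter
  independent of `n_genes`.
* **Promoter classes**: proportions 0.45 / 0.465 / 0.015 / 0.07 (active
  both / inactive both / exclusively pre-pro-B / exclusively pro-B),
  echoing the relative magnitudes of the real class counts.
* **Scores**: active promoters draw cRPKM targets from
  10^N(1.7, 0.3) clipped to ≥ 12; inactive from 10^N(−0.15, 0.35) clipped
  to ≤ 5. The clips keep the true classes realizable at the fixed cutoff
  of 8 — without them a tail of "active" promoters would sit below the
  cutoff by construction and no method could recover the labels. The
  resulting mixture has its antimode near the cutoff.
* **ChIP tags**: the K4 share of a promoter's signal is Beta(8,8) clipped
  to [0.25, 0.75] (both marks co-occur at genuinely active promoters);
  counts are Poisson at the target score; positions follow a triangular
  kernel spanning the promoter ± 500 bp, with intensity inflated by the
  kernel's capture fraction so the score measured in the ± 200 bp window
  realises the target. Uniform background fills each library to its
  nominal depth: 2 M tags per pro-B mark, with pre-pro-B depths 70%
  (H3K4me3) and 17% (H3ac) lower — the study's imbalance, which
  reproduces its under-calling of pre-pro-B promoters. A few inactive
  promoters (default 5) receive 20 identical-position tags in one mark as
  amplicon artifacts; their real signal is zero by construction.
* **Transcription**: expected RPKM from 10^N(1.3, 0.4) (active) and
  10^N(−1.3, 0.4) (inactive) — ~2.5 orders of magnitude apart at the
  medians — with a small per-state wiggle (σ = 0.05 log₁₀) for
  non-differential genes. GRO counts are Poisson at
  rate × length_kb × depth_M (5 M per state); the table header carries the
  nominal depth, the model being a genome-wide library of which the
  annotated genes are quantified.
* **Stability and modes**: a log-normal stability multiplier
  (σ = 0.25 log₁₀), with 5% of plain active genes unstable
  (multiplier ≈ 10^−1.5) in one state or both. Active-in-both genes draw a
  regulatory mode (90.6% no protein change, 2.8% transcriptional, 5.5%
  post-transcriptional split 1:2 mRNA-level:downstream, 1.1% ambiguous —
  the proportions of the real Table-1 "active in both" column); exclusive
  classes are transcriptional with probability 0.55. Driven folds are
  log₂-uniform on [1.5, 3] (RNA axes) and [1.0, 2.5] (protein); ambiguous
  genes get a transcription fold whose stability change cancels it at the
  mRNA level. One designated active-in-both gene has protein effect
  −log₂ 24 with flat transcription, mRNA and stability. FPKM observation
  noise is log-normal (σ = 0.08 log₁₀) with a detection limit of 0.02;
  peptides (1–10 per gene, 60% of genes detected, 3% ambiguous rows)
  scatter around the true effect with σ = 0.25 log₂.
* **Truth states**: the per-gene true axis states and broad group are
  derived from the noiseless expected measurements through the same
  classification rules at default thresholds, so the noise-free limit
  (`noise_scale = 0`, which switches off count sampling, background,
  measurement noise and peptide scatter) reproduces them exactly.

What the generator does **not** emulate: mappability and alignment error,
fragment-length effects (tags are rawlength, 36 bp), copy-number or GC
bias, isoform structure (one TSS per gene, whole-span quantification),
correlated peptide detection (detection is uniform across genes rather
than abundance-weighted), and compositional coupling between libraries.
Passing recovery tests therefore demonstrates the pipeline's correctness
under the stated statistical structure, not robustness to artefacts real
sequencing adds.

## Problem sizes and determinism

The standard validation fixture is 5,000 genes at default noise
(≈ 6.3 M ChIP tags across four libraries); the noise-free fixture uses 600
genes; interval-enrichment validation scores 200,000 random 400 bp windows
(a scaled version of the study's one million, at the same windows-per-Gb
order); the projection-test calibration uses 2,000 simulated null sets of
400 midpoints against a reference covering 25% of a toy chromosome, a
design where the discrete minlike test's exact level (0.0497) is close to
nominal. All randomness flows from explicit seeds; rerunning any stage
with the same config is byte-identical.

## Known limitations

* The activity cutoff is treated as a constant of the method; the antimode
  estimator justifies it but does not feed back into calling.
* The single-mark rule's constants are heuristics for a phenomenon the
  source analysis described only qualitatively.
* Gene-level GRO quantification over whole spans will merge overlapping
  genes on the same strand; the generator avoids overlaps, real
  annotations do not.
* The relative-distance statistic is binned; with very few queries the
  Monte-Carlo p resolution (1/(resamples+1)) dominates.
* iTRAQ ratio compression (systematic underestimation of true fold
  changes) is not modelled; protein folds are taken at face value.
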