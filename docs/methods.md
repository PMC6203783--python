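# Methods

This note documents the models, conventions and design choices behind the
package, what the synthetic-data generator does and does not emulate, and
the known limitations. Every number quoted here is computed by the test
suite or `scripts/acceptance.py`; nothing is asserted that the code does
not measure.

## Quantification

Counts are normalized per library as reads/fragments per kilobase per
million mapped (`value = count × 10⁹ / (length_nt × library_size)`), with
the realized library size (column sum) as the denominator. TE per gene and
condition is the ratio of replicate-mean Ribo-seq RPKM to replicate-mean
RNA-seq FPKM; genes are eligible only when every replicate of both assays
is nonzero in that condition. Genes with zero mean RNA but nonzero Ribo
get an undefined TE (NaN), never infinity. Percentile thresholds (20th /
80th for the low/high TE sets; quartiles later) use linear-interpolation
(type-7) quantiles with strict inequalities, so ties at the threshold are
excluded and an all-equal input yields empty sets. Replicate correlations
are computed on the normalized values directly; a `log2(x+1)` transform is
available as a flag but is not the default.

Because TE is a ratio of two depth-normalized quantities, it is inherently
a *relative* measure: any global rescaling of one assay's library sizes
cancels. The generator accounts for this by centering planted TE values by
their expression-weighted mean (below), so that the recovered ratios match
the stored truth without a global scale factor.

## Negative-binomial differential test

The differential engine is self-contained and intentionally simple:

1. **Size factors** by the median-of-ratios method over features with
   all-positive counts.
2. **Dispersion** per feature by method of moments on normalized counts,
   pooled *within* condition groups (so planted fold changes do not
   masquerade as dispersion), with a trend `α(μ) = a₀ + a₁/μ` fitted by
   least squares across features. The plug-in value is
   `max(trend, per-feature moment)` — a deliberately conservative choice:
   it keeps the Wald test at or below nominal size with the study's two
   replicates per condition (measured type-I ≈ 0.03 at α = 0.05 over 200
   null features with dispersion 0.1), at a negligible power cost for the
   large planted effects of interest (power > 0.99 at a planted 8-fold
   change). As dispersion → 0 the test reduces to a near-Poisson z-test
   and tracks nominal size on an α grid.
3. **Fit** per feature by IRLS for the NB GLM with log link and
   log-size-factor offsets; Wald statistic = log2FC / SE from the Fisher
   information; Benjamini–Hochberg correction within each contrast,
   excluding all-zero features from the family.

Gene-level calls use adjusted p < 0.001 and |log2FC| ≥ 1; subsystem-level
analyses use p < 0.01 and run on per-subsystem *summed raw counts* (count
models need counts, not normalized values). The engine's fold-change ranks
are cross-checked against pyDESeq2 in the test suite (Spearman > 0.95 on a
mixed fixture); the external engine is never used in the pipeline itself.

Known behavior: with a minority of same-direction planted changes,
median-of-ratios normalization shifts slightly into the null tail (a
property shared with the standard implementations); simulations in the
test suite therefore plant balanced effects when asserting fold-change
calibration.

## Subsystem percent layers and differential-TE calls

Only subsystem-annotated genes contribute. Within each experiment
(assay × condition) replicate-mean expression is summed per subsystem and
normalized to percent of the annotated total; a cross-condition layer sums
the per-experiment percents over conditions and renormalizes. Subsystem TE
is percent translation / percent transcription per condition. Genes mapped
to several subsystems contribute to each.

A subsystem is heterotrophically differentially efficient when (i) its
translation differs from both autotrophic conditions at adjusted p < 0.01
while the two autotrophic conditions do not differ (p > 0.01), (ii) its
heterotrophic translation percent strictly exceeds the 50th percentile of
that condition's subsystem percents, and (iii) its heterotrophic TE
strictly exceeds its TE in each autotrophic condition. The autotrophic
call mirrors this (both autotrophic p-values < 0.01 versus the
heterotrophic condition — the contrast anchor the method leaves implicit —
both above their own 50th percentiles, both translating above the
heterotrophic level). The "50th percentile" is computed over subsystem
translation-percent values within the condition; single-number subsystem
TEs stand in for replicate means in clause (iii).

## TSS calling

Coverage is strand-specific 5′-end read counts (0-based vectors; bedGraph
interchange). A candidate requires treated ≥ `min_reads` (default 5 — a
documented stand-in for the study's manual curation) and untreated = 0 at
the same position. Candidates across the eight dataset-pairs
(4 conditions × 2 replicates; replicates count as separate datasets, which
is what makes the 1–8 score attainable) are chained within `merge_window`
(default 3 nt, configurable; chosen for ragged 5′ ends) and reported at
the mode position (ties → smallest). Categories: primary within −250..+50
of a start codon on the same strand (nearest start codon wins); internal
in the CDS past +50, sense; antisense on literal ORF overlap of the
opposite strand with no flanking extension; orphan otherwise — with
precedence P > I > A > O so the partition is exclusive and exhaustive.
5′UTR length is the TSS→start-codon distance in transcription orientation;
TSSs at or downstream of the start (0..+50) get length 0 and a
leaderless-like flag. Operon coverage is the closed-form
`100 × mean operonic gene content × n_primary / n_genes`, reported
unrounded.

## RBS energetics and 5′UTR features

The RBS scan slides a 10-nt window over the 25 nt upstream of the start
codon (16 windows) and scores each window's best duplex with the anti-SD
octamer `AAGGAGGU`. "Lowest −ΔG" is interpreted as most negative ΔG
(strongest hybridization), consistent with the affinity-bin axis running
from 0 to −12.7 kcal/mol. Ties break toward the window whose 5′ distance
is closest to the validated modal distance of 13 nt, then toward the most
3′ window.

The default energy backend is a built-in nearest-neighbor RNA:RNA duplex
model at Turner 2004 free energies (37 °C): Watson–Crick and GU-wobble
stacks, tabulated 1×1 interior loops, generic penalties for small bulges
(single-nt bulges keep the flanking stack) and larger interior loops with
NINIO asymmetry, duplex initiation +4.10 kcal/mol, +0.50 per terminal
AU/GU pair, and dangling-end terms at both helix ends; a lone pair is
never stable and energies are clamped at 0. A `vienna_duplex_energy`
adapter exposes ViennaRNA's duplexfold behind the same interface; because
every downstream analysis depends only on energy *ranks*, the test suite
asserts rank agreement (Spearman > 0.95 over 1000 random windows) rather
than absolute equality — the backends differ on rare multi-loop duplexes
and on positive (clamped) energies.

URR AU% is the A+U percent of the 15 nt immediately 5′ of the RBS window,
counted on the coding strand, and is defined only when a primary TSS is
known and lies ≥ 15 nt upstream of the URR 5′ end — the guard against
reading AU-richness off the ~69% AU genomic background. CAI is the
geometric mean of relative adaptiveness `w = f(codon)/max f(synonym)` over
codons, excluding Met, Trp and stops; the reference set defaults to the
top decile of genes by mean Ribo-seq RPKM (an explicit list can be given;
the original reference set is not recorded in the method source). ΔG bins
are 11 equal widths spanning [−12.7, 0] with out-of-range values clamped
to the end bins. Group comparisons use exact Mann–Whitney / Wilcoxon null
distributions for n ≤ 20 and tie-corrected normal approximations
otherwise; both the unpaired rank-sum and the paired signed-rank variants
are provided, since the low/high-TE sets are unpaired while the original
comparison is described as a signed-rank test.

## TE_max trend analysis

TE_max is the per-gene maximum TE over conditions. Filters are strict:
0.01 < TE_max < 5 and mRNA FPKM > 10 (values exactly at a boundary are
excluded). Quartiles use the 25/50/75th percentiles of surviving TE_max.
mRNA bins are equal-count deciles of log2 FPKM (an equal-width flag
exists); equal-count bins keep the per-bin confidence intervals
comparable. The trend regression is OLS of *per-gene* log2 TE on bin
index — bin means ± 95% t-intervals are computed for display only — with
the Wald test of zero slope. The slope difference between quartile groups
is tested primarily through the interaction term of the pooled regression,
with a pairwise z-comparison of the two slope estimates reported
alongside. Category enrichment is a 2×2 Fisher exact test per
(category, quartile) cell at raw p < 0.05 to match the original
presentation, with an optional BH-adjusted column; enrichment is flagged
only when the cell's odds ratio exceeds 1.

## Synthetic data

The generator is the package's study stand-in, not a fixture. Defaults
are the study conditions where stated, and one-time choices elsewhere:

* genome GC 0.311 (the organism's composition); genes packed left to
  right with 60–140-nt spacers, CDS 300–900 nt of GC-weighted sense
  codons, so genes never overlap;
* 5′UTRs of 45–65 nt (bracketing the observed median of ~47 nt and long
  enough for the URR-definedness guard, which needs ≥ 43 nt); each gene
  gets a planted TSS at its UTR start and an RBS of planted quality —
  optimal = the exact anti-SD complement, weak = the 4-nt `CTCC` core,
  absent = a shuffled octamer. The octamer sits one base inside the
  10-nt window whose 5′ end is at distance 13, which gives that window
  both dangling-end bases and makes it the unique energy optimum, so the
  scanner reports exactly distance 13. The 15-nt URR is planted at a
  controlled AU fraction (0.95 / 0.70 / 0.45 by quality);
* planted TE defaults to 3.0 / 1.0 / 0.3 by RBS quality so feature–TE
  associations are recoverable by construction; because RPKM-ratio TE is
  scale-relative, planted TEs are centered once by their
  expression-weighted mean and the *centered* values are stored as truth;
* counts: RNA ~ NB(mean ∝ length × expression × depth, α) with
  variance = μ + αμ², α = 0 meaning Poisson; Ribo mean = RNA mean ×
  TE (optionally × a condition-specific translation effect, which plants
  condition-dependent TE); two replicates share means; depth 10⁶ and
  dispersion 0.1 as the study-scale defaults. RNA and Ribo library-size
  ratios are not fixed by the method source, so they fall out of the TE
  centering rather than being separate dials;
* TSS coverage: eight treated/untreated pairs; planted TSSs receive a
  fixed 50-read pileup in a seeded subset of pairs (support 1–8);
  background noise of 1–3 reads at a low per-base rate, placed ≥ 5 nt
  from planted TSSs in all libraries so the planted truth stays exactly
  recoverable and sub-threshold noise cannot create calls;
* determinism: one `numpy` generator seeded from the spec; identical
  specs give byte-identical outputs.

What the generator does **not** emulate: positional read biases,
rRNA contamination, multi-mapping, operonic co-transcription of counts
(each gene gets its own TSS; operon labels exist only for the coverage
formula), condition-dependent 5′UTR usage, and any coupling between codon
content and expression. Passing tests therefore demonstrate that the
*computations* recover planted structure under the assumed statistical
model, not that the model captures every property of real libraries.

A separate helper (`plant_te_trend`) constructs the expression-dependent
TE pattern directly — four non-overlapping TE_max bands with log2 TE
rising (+0.8 per SD of log mRNA) in the high band and falling in the low
band — because the count-level generator plants a single TE per gene and
cannot express a TE-by-mRNA interaction.

## Numerical choices and degenerate inputs

Coordinates are 0-based half-open internally; GFF3 is emitted/read
1-based inclusive and bedGraph 0-based half-open, with the conversion
centralized in one module. Zero library sizes, zero gene lengths, empty
subsystem maps, < 5 eligible genes for percentiles, < 8 filter survivors,
< 3 occupied bins for a trend, mismatched coverage lengths and malformed
interchange lines all raise explicit errors (with line numbers for
parsers). IRLS caps the linear predictor at ±30 and falls back to a
pseudocount-initialized fit for zero groups. Problem sizes in the tests
and the acceptance script (300 genes, depth 10⁶, 200-feature null panels,
500 calibration replicates, 2000–10000 oracle draws) are chosen so the
whole suite completes in a few minutes on one CPU while keeping Monte-
Carlo error well inside the asserted tolerances.

## Known limitations

* The ratio estimator's sampling noise bounds TE recovery: with two
  replicates × three conditions per assay, Var(log TE) ≈ 2α/6, giving a
  median relative error floor near 13% at dispersion 0.1 and near 9% at
  0.05. The parameter-recovery invariant is therefore asserted at
  dispersion 0.05; at 0.1 the acceptance-level check measures ~12% and is
  reported as such.
* The NB engine is deliberately conservative and does not reproduce
  DESeq2's MAP dispersion shrinkage or LFC shrinkage; it is a documented,
  testable equivalent, not a reimplementation.
* The built-in duplex model omits 2×1/2×2 special loop tables and
  coaxial effects; agreement with a full folding engine is asserted on
  ranks, which is all the downstream analyses consume.
* Real TSS-seq has condition-specific starts and processed-end artifacts
  correlated with expression; the generator's uniform noise does not
  model either.
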