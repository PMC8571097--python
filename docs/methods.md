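# Methods

`chromocall` implements the downstream statistical analyses used to
characterize fusion-oncoprotein binding and chromatin heterogeneity in
KMT2A-rearranged leukemia from antibody-tethered profiling data
(CUT&RUN / CUT&Tag fragments). This note records the models, the
numerical choices, what the synthetic generators emulate, and the known
limitations.

## Coordinates and counting

All coordinates are 0-based half-open (BED convention); the TSS of a
minus-strand gene is `end - 1`. End-abutting intervals do not overlap.
Fragment quantification offers two modes: `any_overlap` (a fragment is
credited to every peak it touches; default for peak quantification) and
`midpoint` (a fragment is credited to the unique window containing
`floor((start+end)/2)`; default for TSS windows and genome bins, where
it prevents double-counting across adjacent windows and conserves total
counts over a tiling). Raw fragment counts feed every statistic; no
depth normalization is applied before the per-sample mixture fits,
because each fit compares peaks or promoters *within* one sample.

## The N-over-C ratio (NCR)

An oncogenic KMT2A fusion retains the protein's N terminus and loses
the C terminus, so a fusion-bound site shows excess N-terminal-antibody
signal. With `n_i`, `c_i` the summed fragment counts from the two
N-terminal and two C-terminal antibody datasets in peak `i`:

    NCR_i = log10( (n_i + min N) / (c_i + min C) ) * F( (n_i + c_i)/2 )

where `min N`, `min C` are the minimum counts over the sample's peak
set (pseudocounts that keep low-count ratios conservative) and `F` is
the right-continuous empirical CDF of the per-peak mean signals,
evaluated at the peak's own mean. `F` acts as a multiplicative
shrinkage factor on the log ratio: a peak with weak total signal has
its NCR pulled toward zero (no evidence) in inverse proportion to its
signal rank, while strong peaks keep their full log ratio. Written
this way the statistic is bounded by the log ratio and the background
forms a single sharp mode at zero, which is what makes the downstream
two-component mixture decision meaningful. A peak with
`n_i + min N = 0` (or a zero denominator) yields an infinite NCR; such
peaks are flagged and excluded from mixture fitting, never imputed.

## The two-component mixture engine

A single univariate two-component Gaussian EM serves every
classification step (NCR, peak widths, promoter counts, per-gene score
bimodality). Implementation details that matter:

* **Initialization.** Four starts by default: a median split and a
  90th-percentile split (per-side moments), then seeded random
  responsibilities. The 90th-percentile start is what lets EM find a
  minority upper component (fusion sites are ~5% of peaks). The best
  final log-likelihood wins; components are relabeled so means ascend.
* **Variance floor.** Component sds are floored at `1e-6 * sd(input)`
  to prevent collapse onto single points. The log-likelihood trace is
  retained on the fit object; it is non-decreasing by construction and
  asserted in tests.
* **Partition decision.** Whether two components are *supported* is an
  explicit decision: EM must have converged, the two-component BIC must
  beat a single Gaussian, and the means must be at least 2 pooled sds
  apart (pooled sd = sqrt of the mixture-weighted within-component
  variance). The separation cutoff of 2 was chosen because the best
  two-component fit of log-transformed *unimodal* count data (the left
  skew of `log10(c+1)` on negative-binomial counts) reaches separations
  up to ~1.7 with a strong BIC advantage, while every genuinely planted
  structure in this pipeline (4x N/C asymmetry, 8x promoter enrichment,
  narrow-versus-wide widths) separates by 3 or more. An unpartitioned
  fit yields zero upper-component calls downstream — this is the
  expected behavior on a fusion-free control sample.
* **Decision rules.** `above_threshold` classifies strictly above the
  density-intersection threshold (the root of the weighted-density
  equality between the means; the weighted midpoint if no root lies
  there) and is used for NCR and widths. `posterior` classifies by
  component membership (responsibility > 0.5) and is used for promoter
  enrichment, where the natural phrase is "residing in the enriched
  component" rather than a cutoff. With unequal component sds the
  posterior boundary is a quadratic, so monotonicity in the count is
  guaranteed only over the observed data range.

## Fusion-site calling

Per sample: NCR mixture and width mixture are fit and assessed
independently; a peak is a fusion site iff it lies above the
intersection threshold in *both*. Widths are fit raw by default
(`log10` available in config). Gene-level targets are genes whose TSS
window (±1 kb) or body is touched by any fusion peak; recurrent targets
appear in ≥ 5 samples of a cohort; a sample's "missing targets" are
recurrent targets absent from its own target set. Genomic categories
use the precedence TSS > gene body > intergenic with ±1 kb TSS windows,
and category shifts between peak sets are tested per category with
two-sided Fisher exact tests on 2×2 tables. Cross-sample structure uses
complete-linkage hierarchical clustering on Euclidean NCR distance and
PCA with samples as observations. Group signal comparisons are
classical two-sample t tests (equal-variance by default, Welch via
config), uncorrected.

## Bivalent-promoter calling

Fragments for H3K4me3 and H3K27me3 are counted (midpoint rule) in ±1 kb
TSS windows. Per mark, the mixture is fit on `log10(count+1)` (count
distributions are multiplicative; raw-scale fits are dominated by the
upper tail), enrichment is posterior component membership, and a gene
is bivalent iff enriched for both marks. If a mark's mixture fails to
partition, no gene is enriched for that mark (and a warning is
emitted), so structureless input yields zero bivalent calls. Group
bivalency fractions (fusion targets / missing targets / controls) come
with pairwise two-sided Fisher tests.

## Chromatin-landscape workflow

Per modification: peak sets are merged (book-ended intervals coalesce);
a regions × samples raw count matrix is filtered with the
lognormal-ECDF rule — fit a lognormal by ML to the positive counts,
then set the threshold to the largest count below the fitted median
whose empirical CDF diverges from the fitted CDF by more than 5%
(absolute difference); entries below threshold are zeroed and all-zero
rows dropped. Restricting candidates to below the *fitted* median caps
the bulk loss when contamination inflates the fitted variance. The
matrix is then `log10(x+1)`-transformed and column z-scored, reduced by
PCA keeping components explaining > 1% of variance, and embedded by
t-SNE with perplexity = nearest integer to sqrt(n rows), duplicates
retained, seeded.

Density-peak clustering of the 2-D coordinates: local density `rho` is
a Gaussian kernel with cutoff distance at the 2nd percentile of
pairwise distances; `delta` is the distance to the nearest
denser point (the global density peak takes the maximum distance);
centers are points with both `rho` and `delta` above their 95th
percentiles; every other point inherits the label of its nearest denser
neighbor in decreasing-density order. The percentile center rule has a
working margin only when dense clusters sit over a diffuse background
(as t-SNE maps of genomic regions do): for isolated equal Gaussian
blobs the 95th-percentile density cut lands at ~0.95 of each blob's
peak — a knife edge — so the clustering fixtures in the tests plant
compact clusters over a uniform scatter and score recovery on the
cluster members.

Per-region lineage assignment takes the lineage group with the maximal
mean z-score (ties to the lexicographically first, flagged). Genome
coverage fractions are merged-bp over genome length.

## Single-cell stage

Cells with < 300 fragments are removed; a Gaussian moment fit
(mu, sigma) to the survivors' FRiP removes cells below `mu - 2*sigma`
(sigma = 0 keeps all). Fragments are midpoint-assigned to 5-kb genome
bins. LSI: binarize, term frequency per cell, idf weight
`log(1 + n_cells/(1 + bin frequency))`, truncated SVD to 30 components;
components with |Pearson r| > 0.9 against log total fragment count are
flagged and dropped before neighbors/UMAP. UMAP is seeded and therefore
deterministic. Raw gene scores sum bin counts over gene body ± 2 kb and
are normalized per cell to 10,000 (deliberately simpler than
distance-weighted gene-activity models; documented simplification).
Imputation is k-NN diffusion: a row-stochastic uniform transition
matrix over each cell's 15 nearest neighbors (self included) in LSI
space, applied t = 3 times — a convex averaging, so imputed values stay
within the neighborhood's raw range. Normalized dispersion is
variance/mean per gene, z-scored within 20 equal-count mean bins (mean
0 within every bin by construction); zero-mean genes are excluded with
a warning. Group dispersion comparisons are two-sample t tests of
normalized dispersion; the control group is the full set of non-program
genes, mirroring the large unbound-control groups used in practice
(comparisons of ~10 genes against ~10 genes are underpowered at
realistic effect sizes). Program covariance: Pearson correlation of
imputed scores among the chosen genes, average-linkage clustering on
`1 - r` cut into two groups, and per-gene "high-cell fraction" = the
fraction of cells above the gene's own two-component intersection
threshold (undefined when that mixture does not partition).

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed); reruns are
byte-identical, and every planted fact is recorded in a
`SyntheticTruth` record.

* **Annotation**: non-overlapping genes, lognormal lengths (median
  20 kb, log-sd 0.5), random strands, Dirichlet-distributed gaps.
* **Fusion experiment** (defaults = the study conditions): 1,000 peaks
  of which 10% are wide and half of the wide ones are fusion sites —
  the proportion observed where ~195 of ~8,000 peaks are wide and about
  half of those carry the fusion signature. Narrow peaks (gamma widths
  around 1.5 kb) sit on TSSs; wide peaks sit in gene bodies clear of
  the ±1 kb TSS window; fusion widths are lognormal with mean 13.1 kb /
  sd 10 kb and ordinary wide domains 8.2 kb / 4 kb. Counts are negative
  binomial with mean proportional to width × depth; depth defaults to
  25 C-terminal fragments per kb (a 1.5-kb peak collects ~10^2
  fragments at 5–10M reads per antibody over ~8k peaks) and NB size 40
  (~16% CV, technical-replicate-scale variation for summed same-target
  antibody datasets). Fusion peaks have N-mean = 4 × C-mean; everything
  else is symmetric. Fragments are emitted so that any-overlap counting
  reproduces the planted counts exactly.
* **Promoter marks**: statuses drawn per gene (defaults 45% K4-marked,
  40% K27-marked, 20% bivalent); enriched windows draw NB counts at 8×
  a background of 8 fragments per 2-kb window. Per-gene bivalency
  probabilities can be fixed per gene group to plant the
  missing-target/target/control rate structure (0.33/0.24/0.14).
* **Landscape**: regions on a synthetic chromosome with shared (high
  everywhere), lineage-blocked (high in one lineage's samples), and
  sample-specific noise regions (high in one uniformly chosen sample).
  Noise regions record a uniformly drawn *nominal* lineage so that
  lineage-assignment accuracy on them measures chance — the negative
  control for the lineage-blocked contrast.
* **Single cells**: each cell runs minority program A (15%) or majority
  program B; its fragments are spread multinomially over genes
  (on-program weight 20, off-program 1, housekeeping 4) and across
  ~2-kb segments within each gene (binarized LSI needs positional
  spread, not count stacks). Cell programs are drawn *first* so that
  the automatically planted unimodal control genes match the realized
  marginal mean of the program-A genes — otherwise the bimodal genes
  monopolize their dispersion mean-bins and within-bin z-scoring
  cancels their own signal. Optional low-FRiP cells emit most of their
  fragments into intergenic gaps.

What the generators do **not** emulate: sequence content, mappability
and GC bias, fragment-length structure, chromatin domain
autocorrelation, doublets, batch effects, and realistic gene-density
heterogeneity. Passing tests therefore demonstrate that the statistics
recover the structure they are designed for at realistic effect sizes
and depths — not that they are robust to every artifact of real
sequencing data.

## Problem sizes and tolerances in the test suite

The suite exercises the pipeline at desk scale: 1,000-peak fusion
samples (100 fusion-free control replicates at 300 peaks), 2,000- and
11,500-gene promoter cohorts, 1,500-region landscapes, and single-cell
runs of 300–1,000 cells on a 6-Mb genome with 120 genes. Mixture
parameter recovery is asserted to ±0.15 on means and ±0.05 on weights
at n = 2,000; at a component separation of 2 sd these tolerances sit at
roughly the sampling sd of the mixture MLE itself (verified against an
independent EM implementation), so that case documents the estimator's
precision limit rather than a bug — at separations 3 and 4 the
tolerances hold with large margin.

## Known limitations

* The partition decision is a heuristic; its separation cutoff is
  config-exposed and calibrated to this pipeline's data shapes, not a
  general bimodality test.
* The lognormal filter assumes a lognormal bulk; strongly multimodal
  count distributions can push the threshold into the bulk.
* The density-peak percentile rule can merge or split clusters on maps
  without a diffuse background (see above).
* Gene scores ignore distance weighting and regulatory elements outside
  gene body ± 2 kb; imputation is deliberately the simplest diffusion
  smoother and is not numerically equivalent to published imputation
  tools.
* Exact parity with any published per-sample site counts is out of
  scope: those depend on raw external data, alignment and peak-calling
  choices upstream of this package.
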