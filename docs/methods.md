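# Methods

`cytopheno` re-implements, as a tested pipeline, the single-cell
phenotype-landscape analysis used for mass-cytometry profiling of
patient-derived tumour xenografts (PDTXs): suspension mass cytometry
(CyTOF) gives per-cell intensities for ~30 antibody markers organised in
four subpanels — human tumour compartment (HTC), mouse stroma compartment
(MSC), oncogenic signalling activation (OSA) and cell cycle / apoptosis
(CCA). The pipeline clusters cells into phenotypes, quantifies
within-model diversity, transfers the phenotype labels to other platforms
(imaging mass cytometry, treated samples, external cohorts), tests their
spatial organisation, and links phenotype composition to genomic
alterations, drug response and survival.

Because the original cohort data are access-controlled, the package ships
a synthetic-data generator that reproduces the statistical structure the
analysis assumes, with known ground truth, so every stage can be
exercised and validated at desk scale.

## Synthetic data model

Each phenotype is a Gaussian template on the arcsinh intensity scale.
The variance hierarchy mirrors the marker subpanels:

* **HTC / MSC (lineage)** — means differ between phenotypes, small
  within-phenotype sd (0.25). Human phenotypes sit at arcsinh means ~3 on
  HTC markers and low (0.3) on MSC; the mouse-stroma phenotype is the
  reverse. The minimum pairwise Euclidean distance between phenotype HTC
  mean vectors is pinned to `separation x sd`; the default separation of
  8 is the "well-separated" preset, at which (a) Monte-Carlo Bayes error
  of lineage classification is far below 1%, (b) nearest-centroid
  transfer on a 10-marker subset rejects well under 10% of cells at the
  0.9 posterior-gap threshold, and (c) within-model CV ordering (below)
  holds.
* **OSA** — means nearly common across phenotypes (base 1.8), sd 0.55:
  signalling varies within a model, not between phenotypes.
* **CCA** — base 1.3, sd 0.9, the most variable subpanel.

This construction makes the within-model mean coefficient of variation
ordered CCA > OSA > HTC, the qualitative pattern the analysis reports for
real PDTXs. Intensities are clipped at zero (ion counts are
non-negative), a mild, documented departure from Gaussianity. Markers
are independent within a phenotype; real antibody panels have correlated
readouts, so passing tests bound recovery under independence only.

Model compositions: human phenotype proportions are Dirichlet(1); the
stroma fraction is an independent Beta(2, 30) draw (mean ~6%). Stroma is
kept structurally minor because xenografts are dominated by human tumour
cells; a Dirichlet weight alone occasionally produced stroma-dominated
models, which no real PDTX shows. Per-model phenotype counts are
multinomial in the composition; default sampling depth is 1,600 cells per
model (49 models x 1,600 = 78,400 cells at full scale).

Spatial catalogues place cells in a rectangle (default 600 x 600 µm):
uniform for `spatial_mode="random"`, a Thomas process (uniform parents,
mean ~20 offspring each, Gaussian scatter sd = `cluster_scale`, default
20 µm) for clustered phenotypes; points falling outside the field are
redrawn from the same process.

Dose-response plates follow a Hill viability curve scaled between plate
controls (positive control = untreated intensity) with Gaussian noise.
Drug AUC values are linear in phenotype log-ratios plus noise, clipped to
[0, 1]; survival times are Weibull (shape 1.5, scale 60 months) with the
log hazard shifted by γ·log-ratios and independent censoring (each case
censored with the stated probability at a uniform fraction of its event
time). Alteration tables are per-model Bernoulli draws whose logit
shifts when the model's dominant phenotype matches a linked gene.

All randomness descends from one integer seed through named substreams
(`templates`, `cells`, `space`, `plates`, `auc`, `survival`,
`alterations`), so stages regenerate independently and bit-identically.

## Pre-processing

The canonical chain, enforced in order by stage stamps on the cell table:
arcsinh transform (cofactor 5, the CyTOF community convention; the
original work does not state one) → per-sample removal of cells whose
median marker signal leaves [median − 2·IQR, median + 2·IQR] → discard of
samples with fewer than 500 cells (configurable; no published threshold
exists) → cosine (unit L2) normalisation per cell → equal-depth
downsampling per model. The ±2·IQR rule is not exactly idempotent — the
IQR shrinks slightly after truncation — so a second pass may remove a
sliver (<0.5%) of borderline cells; this is a property of the rule, not
of the implementation. Batch concordance of reference samples is
quantified by per-marker signed EMD between batch replicates. An
alternative chain (log2, cosine, per-marker z-scale) matches how external
imaging cohorts are processed.

## Clustering and diversity

A k-nearest-neighbour graph (exact Euclidean neighbours, ties by index)
is reweighted by the Jaccard overlap of neighbour sets and partitioned by
modularity maximisation. Leiden is the default optimiser with Louvain as
an option: both maximise the same objective, but plain Louvain left
clearly split partitions on well-separated synthetic phenotypes that
Leiden resolves. Stability of a neighbourhood size k is measured by
re-clustering 90% subsamples (100 repetitions at full scale) and
computing the adjusted Rand index on the shared cells of every pair of
runs — the intersection is the only label-comparable set.

The full-scale neighbourhood size is k = 250 at 78,400 cells. For desk
scale we scale k proportionally with a floor of 80,
`k = max(80, round(250·n/78400))`: with fewer neighbours the modularity
resolution limit starts splitting genuine phenotypes (measured directly
on synthetic data at the 10,000-cell test scale: k = 32 split a true
phenotype in ~30% of subsample runs, k = 50 still split phenotypes
holding ~40% of the cells at some seeds, while k = 80 recovered all
phenotypes across every seed tried). Even at k = 80 the subsample
stability scan remains sensitive to the composition draw: when one
phenotype holds ~40% of the cells, split partitions of it carry
marginally higher modularity than the true one, and the median pairwise
subsample ARI ranges roughly 0.8-1.0 across cohort seeds. This is the
resolution-limit behaviour of modularity itself, and the reason the
published procedure scans k by exactly this stability measure.

Diversity of a model's composition over the human phenotypes is Simpson's
score `1 − Σ p_i²` (0 = homogeneous). Subpanel variability is the
per-model mean CV per subpanel with paired two-sided t-tests between
subpanels. Cluster annotation applies first-match threshold rules to
centroid medians (mouse stroma via MHC-I high / CD298 low; luminal via
EpCAM and E-cadherin; mesenchymal via Vimentin high / EpCAM low).

## Cross-platform label transfer

A model-specific nearest-centroid classifier in the nearest-shrunken-
centroid family with shrinkage disabled: classes are the phenotypes with
training prevalence > 5%; centroids are raw class means on the shared
markers; the discriminant is

    δ_k(x) = Σ_j (x_j − c_kj)² / (s_j + s0)² − 2 log π_k

with pooled within-class sd s_j, stabiliser s0 = median_j(s_j), priors
π_k equal to training proportions (uniform optional). Posteriors are the
softmax of −δ/2; a cell is "unclassified" when the gap between the two
highest posteriors is below 0.9. A 10-fold cross-validated training
accuracy is reported as a diagnostic only — with shrinkage disabled there
is no parameter to tune. Transfer is validated by Pearson correlation of
test-side vs training-side class centroids, matching against
non-matching. The classifier stores its declared transform chain so that
target data must be processed the same way as training data.

## Spatial autocorrelation

For each phenotype with at least 100 cells in an image, the Davis &
Peebles ratio w(r) = (N_R/N_D)·DD(r)/DR(r) compares data–data pair counts
to data–random counts against N_R = N_D uniform points in the image
region (the stated rectangle, else the convex hull of the image's cells —
recorded in the output). Bins default to 0–200 µm in 10 µm steps. w = 1
under complete spatial randomness; w > 1 at small r indicates clustering.
The reported uncertainty combines the spread over random realisations
with the Poisson term of the fixed data–data counts, `w/√DD`, in
quadrature — realisation spread alone understates the null variation
because DD does not vary between realisations. An image/phenotype is
flagged as clustered when mean w exceeds 1 by more than 2 sd in any bin
below 50 µm (configurable).

## Association statistics

* **Signed EMD**: both samples histogrammed on one grid (bin width 0.1 on
  the arcsinh scale, padded one bin each side); EMD is the integrated
  |CDF difference|, signed by the treated-minus-control median shift. It
  agrees with the exact 1-D Wasserstein distance to within one bin width.
* **DREMI** (density-resampled mutual information, bits): joint density on
  a 20×20 grid from the distance to the k-th nearest data point (k = 10;
  k = 5 leaves a ~0.15-bit positive bias under independence), each X
  column renormalised to p(Y|X), MI computed with uniform weight per
  occupied X bin. Constant inputs return a flagged 0.
* **Alteration enrichment**: for each (phenotype, alteration), the overlap
  between the phenotype's cells and cells from altered models is tested
  with the upper-tail hypergeometric (a doubled-tail two-sided option
  exists), Bonferroni-adjusted over all pairs, significance at adjusted
  p < 0.01, with an optional >0.25 prevalence display filter. Cells are
  the test units, as in the original design, so the test is exact only
  when cell labels are exchangeable across models; when compositions vary
  model-to-model the cell-level test is anti-conservative
  (pseudoreplication) — the calibration check therefore uses
  composition-homogeneous models for its null.
* **Gene-set enrichment**: genes ranked by Pearson correlation of
  expression with phenotype prevalence across models; weighted
  running-sum enrichment with a set-size-preserving gene-permutation
  null (NES, FDR; significant at FDR < 0.01), via gseapy's preranked
  machinery. Gene sets are read from GMT.
* **Drug correlations**: two-sided Spearman tests of phenotype prevalence
  against per-model AUC, requiring ≥10 overlapping models per drug.

## Drug response and compositional models

Percent response is `100 − 100·(I − neg)/(pos − neg)`; a non-decreasing
isotonic regression of pooled replicate responses on log10(dose) is
integrated by the trapezoid rule and normalised by 100 × the log-dose
range, giving AUC ∈ [0, 1] (responders > 0.2). The isotonic direction
(non-decreasing in dose) and the log-dose axis are the package's choices;
neither is stated in the source analysis. Drug quality filters: <33% of
curves in degenerate shape clusters (flags supplied externally), ≥10
models tested, both a responder and a resistant model present.

Compositions enter models as additive log-ratios
`log((p_i + pc)/(p_ref + pc))` against a referent phenotype; the default
pseudocount 0.5/1600 is half a cell at the default sampling depth and
keeps zero prevalences finite. The AUC model is an L1-penalised linear
regression (predictors standardised internally, λ at the minimum of
10-fold CV error, not 1-SE; pure L1 because the analysis selects a subset
of variables), reported with full-data R² and the selected support. The
survival model is an L1-penalised Cox proportional-hazards fit: the λ
path comes from an elastic-net Cox solver (l1_ratio = 1) and λ is chosen
at the minimum 10-fold cross-validated partial-likelihood deviance,
computed with the Breslow tie convention. Risk scores (linear
predictors) are cut at their quartiles (ties to the lower group) for
Kaplan-Meier curves and a 4-group log-rank test.

## Problem sizes and numerical choices

Tests and the acceptance script run the stages at desk scale, chosen so
each property is measured with adequate power: clustering recovery at 20
models × 500 cells with a 20-repetition stability scan; transfer at 10
models × 800 cells with 500-cell targets; spatial estimates on
1,500-point catalogues with 10 random realisations; enrichment and lasso
calibrations over 50–100 seeded replicates; the Cox cohort at n = 480
cases with a 200-replicate null. Degenerate inputs follow explicit
contracts: zero-norm cells pass cosine normalisation unchanged and are
counted; models with no cells in a prevalence subset give flagged zero
rows; constant DREMI inputs return flagged zeros; fewer than 4 distinct
risk scores make quartile grouping an error rather than a silent
collapse.

## Known limitations

* The generator's marker independence and Gaussianity (with zero
  clipping) understate the heavy tails and correlation structure of real
  CyTOF data; recovery rates here bound the idealised, not the real,
  case.
* The cell-level hypergeometric inherits anti-conservatism under
  between-model composition heterogeneity (see above).
* The two-point estimator uses no edge correction beyond the data–random
  normalisation; w at radii comparable to the field size is biased for
  any estimator of this form.
* FCS support covers the subset the pipeline writes (single dataset,
  list-mode float32); vendor integer formats are out of scope.
* No attempt is made to reproduce the published cohort's cluster count or
  headline statistics, which depend on the access-controlled data.
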