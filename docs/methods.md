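# Methods

`imgx` implements a transcriptome–neuroimaging spatial-association
pipeline: it asks whether the spatial pattern of gray-matter-volume (GMV)
group differences across the brain co-varies with the spatial pattern of
gene expression measured at post-mortem tissue-sample locations. This
note documents the statistical model of each stage, the tunable
parameters, the synthetic-data generator used for testing and
calibration, and the numerical choices made where the design was open.

## Pipeline model

### Expression reduction

Input is a multi-donor microarray file set in the Allen-atlas dialect
(per-donor probe×sample expression, binary present/absent (PA) calls,
probe→gene table, MNI sample coordinates) plus an RNA-seq reference
table. The reduction is:

1. **Background filter.** A probe is kept iff its PA call is 1 in at
   least `min_present_fraction` (default **0.5**) of all sample sites
   pooled across donors.
2. **Probe selection.** For each gene present in the RNA-seq reference,
   the probe whose expression profile has the highest Spearman
   correlation with the gene's RNA-seq profile over shared samples is
   kept; genes without an RNA-seq entry are dropped. Spearman is used
   because the two platforms differ in scale; only rank agreement is
   meaningful.
3. **Hemisphere restriction.** Only samples with MNI x strictly < 0 are
   retained. The midline (x = 0) is excluded: its hemisphere assignment
   is ambiguous and a strict rule is deterministic.
4. **Normalization.** Within each donor and gene, a scaled robust
   sigmoid: s = 1/(1 + exp(−(x − median)/(IQR/1.35))), followed by
   min-max rescaling to [0, 1] within the donor. Both steps are monotone
   (ranks preserved) and location/scale-free, which removes per-donor
   batch offsets; no cross-donor quantile matching is applied beyond
   this. A zero IQR falls back to rank-based scores. Donors are then
   concatenated sample-wise.

The result is a samples × genes matrix in [0, 1] keyed by sample (well)
ID; all downstream joins are by ID, never position. The risk-gene list
(a user file; a 52-symbol default assembled from the AD GWAS literature
is packaged) is intersected with the matrix's gene background to give
the "interesting" genes.

### Group contrasts

Each contrast (e.g. patient group vs controls) is a voxelwise GLM with
intercept, group indicator and covariates (gender by default, coded
0/1); the reported t belongs to the group indicator, positive t meaning
group A > group B, with df = n − rank(design). The implicit analysis
mask keeps voxels whose cohort mean exceeds 10% of the maximum,
intersected with the brain mask.

Cluster-level familywise correction follows stationary random-field
theory. Residual-field smoothness is estimated per axis from normalized
residuals: at each voxel the residual vector across subjects is scaled
to unit norm, and the mean squared forward difference along an axis
estimates 2(1 − ρ(1 voxel)); inverting the Gaussian autocorrelation
ρ(δ) = exp(−δ²/4σ²) gives the FWHM. The search region is summarized by
Worsley lattice resel counts R0–R3. For each tail separately (the
decrease and increase analyses are two one-tailed corrections, matching
how VBM results are reported), the cluster-forming threshold is the t
quantile at `voxel_p` (default **0.001**); components are labeled at
26-connectivity (configurable 6/18/26); the expected cluster count E[m]
is the resel-weighted sum of t-field Euler-characteristic densities; the
expected suprathreshold volume gives the mean cluster size n̄; cluster
sizes follow the classic P(n ≥ k) = exp(−βk^(2/3)) tail with
β = (Γ(5/2)/n̄)^(2/3); and the familywise p of a size-k cluster is the
Poisson-clumping probability 1 − exp(−E[m]·exp(−βk^(2/3))). Clusters
with p < `cluster_p` (default **0.05**) survive. A label-permutation
alternative (`permutation_cluster_correct`) is provided for validation;
it is assumption-free but much slower. Cross-contrast consistency masks
are voxelwise intersections of same-sign corrected masks.

The analytic correction is validated by simulation rather than by
equivalence to any particular neuroimaging tool: on 200 null cohorts the
observed per-tail familywise rate is ~0.04 at nominal 0.05 (the
acceptance suite asserts ≤ 0.10).

### Regional extraction

Each tissue sample's regional T is the mean t over in-mask voxels whose
centers lie within `radius_mm` (default **4.5 mm**, three voxel widths)
of the sample's MNI coordinate — Euclidean distance in world mm,
boundary inclusive. Out-of-mask voxels are excluded from the mean rather
than zero-filled (zero-filling would bias edge samples toward 0).
Samples with no in-mask voxel are dropped, and the same IDs are dropped
from the expression matrix. An interior sphere on a full 1.5 mm lattice
covers exactly 123 voxels; the implementation is tested for exact
equality against a brute-force enumeration of every voxel.

### PLS association and gene ranking

With X the per-gene z-scored expression of the interesting genes and y
the centered regional T profile, the first PLS component for a single
response has the closed form w ∝ Xᵀy (unit norm); scores are Xw,
sign-oriented so corr(scores, y) ≥ 0. Per-gene z-scoring makes weights
comparable across genes whose [0, 1] normalized ranges differ.

Gene reliability is assessed by bootstrap: samples are resampled with
replacement `n_boot` times (default **1000**; the recovery harness uses
500), each replicate refit and sign-aligned to the full-data weight
vector by the sign of their dot product — without this alignment the
component's sign indeterminacy inflates the SE and collapses Z. The SE
is the per-gene SD of replicate weights and Z = weight/SE. Genes with
Z > `z_thr` (default **5**) or Z < −`z_thr` form the positive/negative
lists; the fixed |Z| > 5 cut is the multiple-comparison control at this
stage (no additional FDR layer). Consistent genes are the intersection
of the signed lists across contrasts, first-list order preserved.
Bootstrap unit is the tissue sample (the only exchangeable unit here).

### Gene-wise statistics

For each consistent gene and contrast, Spearman correlation
(average-rank ties) between expression and regional T, two-sided p by
the t approximation (exact permutation enumeration for n ≤ 8; full
enumeration beyond that is infeasible). Significance uses a Bonferroni
threshold alpha/n_tests with `n_tests` defaulting to the number of
consistent genes (0.05/12 = 4.17 × 10⁻³ in the canonical configuration)
and a strict `<` comparison.

### Enrichment

Over-representation of a query list against GMT gene sets restricted to
the analysis background (the expression matrix's genes — the same
universe in which the interesting genes were defined, not the whole
genome): upper-tail hypergeometric p, enrichment factor (k/n)/(K/N),
survivors require overlap ≥ `min_overlap` (default **3**) and
p < `alpha` (default **0.05**); no further multiplicity correction is
applied at this stage. Surviving terms are grouped by Cohen's kappa
between their membership indicator vectors over the background
(absent–absent pairs count as agreement), average-linkage clustering on
1 − kappa, tree cut at kappa ≥ `kappa_thr` (default **0.3**); each
cluster is labeled by its lowest-p term, ties broken lexicographically.

## Synthetic-data generator

The generator fabricates every input with known ground truth so the
whole chain is testable and calibratable offline.

**Cohort.** Per subject, white Gaussian noise is smoothed to
`smoothing_fwhm_mm` (default **8 mm**) with periodic boundaries — the
field is then stationary everywhere by construction, which is exactly
the assumption of the random-field correction, making the generator a
valid calibration oracle — and rescaled to unit SD. Planted effects are
spherical indicators convolved with the same kernel and rescaled to unit
peak, so a cluster with effect size d shifts the peak-voxel group mean
by exactly d noise-SDs (expected peak two-sample t ≈ d·√(n/2) ≈ 9.66 at
d = 1.5, n = 83/83). Gender is Bernoulli (P(F) = 45/83, the canonical
cohort's ratio) with a small additive male offset (0.05 SD) so covariate
adjustment is exercised. Defaults: 1.5 mm voxels, 83 subjects per group,
groups NC/EMCI/LMCI/AD, grid 40×48×40 (chosen once as the smallest grid
holding two 6 mm clusters plus 8 mm smoothing without boundary
interaction), ellipsoidal brain mask.

**Expression.** Tissue-sample coordinates are drawn uniformly within the
brain mask in both hemispheres (twice the left-target count, default
target **1285** retained left samples), split over **6** donors. The
true spatial distribution of retained atlas samples is unknown;
uniform-in-mask is a stand-in sufficient for property testing. For a
planted gene with target correlation ρ, the latent profile is
ρ·z + √(1−ρ²)·ε where z are normal scores of the atrophy-field values at
the sample coordinates — a Gaussian-copula construction, so the target
is (approximately) on the Spearman scale regardless of the field's
skewed, tie-heavy distribution. Default planting: 8 genes at ρ = +0.4
and 4 at ρ = −0.4, named after well-known AD risk genes so the demo
output reads naturally. Each gene gets one high-fidelity probe (unit
slope, SD 0.15 noise, absent-rate capped below 0.5 so every gene can
survive the background filter) and two degraded probes (slope 0.2–0.6,
heteroscedastic noise SD 0.8–1.5, Beta-distributed absent rates with
mean `pa_dropout` = 0.3), exercising both probe filters. Donors differ
by random affine (offset/scale) batch shifts, which the SRS
normalization must remove. The RNA-seq reference covers the risk genes
always and ~90% of filler genes, over 120 wells of the first two donors.

**Gene sets.** One planted term per signed list (planted genes plus two
random extras) among random draws, written as GMT.

What the generator does **not** emulate: cortical anatomy and realistic
atrophy topography; spatial autocorrelation of expression between nearby
samples (profiles are conditionally independent given the field —
real expression maps are smooth, which inflates effective significance;
the pipeline inherits the field-standard practice of ignoring this, see
Limitations); donor-specific sample-placement geometry; probe-level
cross-hybridization. Passing tests therefore demonstrate correctness of
the inference machinery under its own assumptions, not robustness of the
biological conclusions to violations of them.

## Numerical choices and degenerate inputs

- Seeds: every random stage takes an explicit seed; the pipeline derives
  per-stage seeds from the config seed, and identical configs reproduce
  byte-identical output trees. NIfTI is written uncompressed (`.nii`)
  because gzip containers embed fields that break byte-level
  reproducibility.
- The t threshold is Gaussianized exactly at the quantile level;
  EC densities use the t-field forms, so low-df calibration holds.
- FWHM estimates below the voxel size are clamped to it (with a
  warning); flat residuals are an error.
- Constant gene columns are dropped from PLS with a warning; a zero
  bootstrap SE excludes a gene from the signed lists; constant inputs to
  correlation functions raise.
- Ties: Spearman uses average ranks throughout; enrichment sorting
  breaks p ties by term ID; kappa cluster labels break p ties by term
  ID.
- Problem sizes used by the test suite and acceptance script (chosen for
  a single-CPU workstation): null cluster calibration uses 200 cohorts
  of 20 + 20 subjects on a 32³ grid; null bootstrap uses 20 runs of 40
  genes × 500 samples; recovery runs use the canonical 83/group with 500
  bootstrap replicates.

## Limitations

- Spearman p-values across ~1285 tissue samples treat samples as
  independent; spatial autocorrelation makes them anti-conservative.
  Autocorrelation-preserving nulls (spin/variogram surrogates) would be
  stronger and are deliberately out of scope.
- The GRF cluster p uses the expected-cluster-count and cluster-size
  tail approximations for stationary fields; nonstationary correction
  and TFCE are not implemented (the permutation alternative covers
  validation needs).
- The expression matrix is bounded in [0, 1] by construction, so signs
  of correlations with signed t-maps are interpretable, but absolute
  expression levels are not comparable across genes.
- Between-donor harmonization is within-donor SRS only; residual
  donor-by-gene interactions are not modeled.
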