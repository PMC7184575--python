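# Methods

`mkgblup` implements a multi-environment grain-yield prediction analysis for
inbred wheat panels that combines genomic relationship information with
field-measured physiological traits in multi-kernel BLUP models, evaluates
them by population-structure-aware cross-validation, and ranks the
physiological traits by penalized regression. This note records the models,
the numerical choices, and what the synthetic-data generator does and does
not emulate.

## Data model

The unit of analysis is a panel of inbred lines grown in an un-replicated
augmented design: each test entry appears once per environment, assigned to
a block, while a small set of check varieties is repeated in every block and
supplies the within-environment error information. Genotypes are biallelic
SNP dosages in {0, 1, 2} with missing calls allowed; phenotypes are
plot-level records of grain yield (GY, kg ha⁻¹), days to heading (DTH), and
physiological traits: SPAD chlorophyll content, canopy temperature (CT),
membrane thermostability (MT), and NDVI at six time points with thermal-time
stamps.

## Derived physiological traits

* **MT** = (1 − T1/T2) × 100, where T1 is the electrolyte-leakage
  conductivity after heat treatment and T2 after autoclaving. T2 must be
  positive; values with T1 > T2 are flagged, not rejected.
* **AGDD** (accumulated growing degree days) is the cumulative sum of
  max(0, (Tmax + Tmin)/2 − Tbase). The base temperature defaults to 0 °C —
  a common choice for winter wheat — and is configurable, since no single
  convention is universal.
* **RS** (rate of senescence) is the slope m of the ordinary least-squares
  line NDVI = m·AGDD + b through a plot's six NDVI/AGDD points (at least two
  non-missing points and nonzero AGDD variance required).
* **SG** (stay-green) is the predicted NDVI at physiological maturity,
  m·AGDD_PM + b, unclipped by default with a warning outside [0, 1]
  (clipping available as an explicit option).

## Phenotype mixed models

Genotype LSmeans are computed per environment by default (genotype fixed in
cell-means coding, block random, optional centered DTH covariate); a joint
variant with environment and block-within-environment random is available.
The per-environment default matches how trait means and correlations are
usually tabulated per site; the joint model and the environment-wise fits
coincide for balanced data.

Broad-sense plot-basis heritability per environment comes from the
all-random model y = μ + genotype + block + ε, with
H² = σ²_G/(σ²_G + σ²_e).

Variance components are estimated by REML implemented in-package: the
residual variance is profiled out, and the restricted likelihood is
maximized over log variance ratios (bounded scalar minimization for one
random factor, Nelder–Mead from three starts for more). Estimates are
truncated at zero before H² is formed, so H² ∈ [0, 1] by construction.
The test suite cross-checks this REML against lme4 (via Rscript) on an
identical augmented-design dataset. Under the augmented design the error degrees of
freedom come almost entirely from the repeated checks, so per-environment
H² estimates are inherently noisy; recovery is therefore assessed as a mean
over seeds.

CT is aggregated to a single plot value upstream of this package (a mean of
repeated readings is assumed where multiple exist). Trait-by-environment
gaps (a trait not measured at a site) are represented as missing columns and
never imputed at the phenotype stage.

## Kernels

* **G = XX′/n** over lines, X the column-centered, column-standardized
  dosage matrix, n the marker count. Standardization uses the population
  (divide-by-N) SD so that trace(G)/n_lines = 1 exactly; this is a
  documented, configurable choice.
* **P = SS′/m** analogously from centered/standardized trait LSmeans.
  Which traits enter P is user-specified; by default all available among
  {SPAD, CT, MT, NDVI_1..6, RS, SG}. Entirely-missing or zero-variance
  traits are dropped with a warning; sporadic per-line gaps are filled with
  the trait mean, each imputation logged, so the construction stays
  auditable.
* Record-level expansion: with Z_g and Z_E the 0/1 genotype and environment
  incidence matrices over (genotype, environment) records, the main-effect
  covariance is Z_g K Z_g′ and the genotype-by-environment (reaction-norm)
  covariance is (Z_g K Z_g′) ∘ (Z_E Z_E′) — the Hadamard product that zeroes
  all cross-environment entries. Every built kernel is checked numerically
  for symmetry and positive semi-definiteness (min eigenvalue ≥ −1e−8 × max).

Marker QC before G: markers with missing fraction > 0.80 or MAF < 0.05 are
removed (ties at the thresholds retained, matching the strict-inequality
reading of the rules); remaining missing calls are imputed by column mean
(fractional dosages) or major allele. An optional Fisher exact allelic
filter — off by default because it belongs upstream in SNP calling — tests
per marker whether the two alleles are independent across lines, using the
2×2 table of per-line allele presence in which a missing call contributes to
the "neither allele" cell; markers are kept iff P < 0.001 (dependent
alleles, i.e. a genuine biallelic locus in inbreds).

## Multi-kernel BLUP

Six models combine the kernels around fixed environment effects:
G; G+GE; G+PE; P; P+PE; P+GE. Each random vector u_k over records is
N(0, σ²_k K_k); residuals are i.i.d. N(0, σ²_ε) (homogeneous across
environments — heterogeneous residuals are a known limitation).

Fitting is by Gibbs sampling:

* Each kernel is eigendecomposed once per fit; eigenvalues below
  1e−8 × max are dropped (reduced-rank sampling). Effects are sampled in
  the eigenbasis, where with complete data the coordinate full conditionals
  are independent normals — one O(n·q) matrix-vector pair per kernel per
  sweep.
* Variance components have scaled-inverse-χ² full conditionals with prior
  df = 5 and scales set from the phenotypic variance so the prior modes
  split it equally among the kernels and the residual (configurable; any
  component can instead be pinned at a fixed value, which is the degenerate
  prior used in the oracle checks).
* Missing phenotypes are treated as latent and refreshed from their
  conditional N(fitted, σ²_ε) each sweep (data augmentation). This yields
  the same posterior for parameters and effects as subsetting the
  likelihood, keeps every full conditional in closed form, and makes the
  kernel eigenbases independent of the missingness pattern — so
  cross-validation reuses one decomposition across folds.
* Default chain: 12,000 iterations, 2,000 burn-in, thinning 5; entirely
  seed-reproducible. The pipeline and the evaluation studies below use
  shorter chains (1,500–4,000 iterations) because the posterior means
  stabilize quickly for these model sizes; chain settings are explicit
  everywhere.

A line's GEBV is the posterior-mean sum of its record's random effects
(fixed environment effects excluded by default).

## Evaluation

Lines are stratified into k = 10 genetic groups by the clustering stage of
DAPC: principal components of the standardized marker matrix (the smallest
number explaining ≥ 80% of variance by default) followed by k-means. The
discriminant step of DAPC is omitted — only the partition matters for fold
construction. Whole groups are assigned to f = 5 folds greedily (largest
group into the currently smallest fold), so related lines never straddle
the training/validation split.

For each fold every record of each validation line is masked across all
environments, the model refit, and predictions correlated (Pearson) with
observed LSmeans within each environment on validation lines only.
Accuracy is adjusted by heritability, r_GY = r_p/√H², with
SE = σ_rp/√(f·H²). When LSmeans are DTH-corrected, the H² of raw GY is
used by default (flagged), since the heritability of the corrected trait is
not separately defined here.

Response to selection uses the breeder's equation R = H²·S with
S = μ_selected − μ_population at 10% selection intensity (ceil of the
fractional count; ties at the cutoff broken by stable line-id order).
By default selection operates per fold on the pooled validation-set GEBVs,
with the fold's validation lines as the reference population, and fold
values are aggregated with SE = σ_RTS/√f; a whole-population refit variant
is available.

## Trait importance

Grain yield is regressed on standardized trait LSmeans under the elastic
net, (1/2n)·RSS + λ[α‖β‖₁ + (1−α)‖β‖₂²/2], over α ∈ {0, 0.25, 0.5, 0.75, 1}
and 50 λ values log-spaced four decades down from λ_max (the smallest
penalty zeroing all LASSO coefficients), with the grid rescaled by 1/α per
mixing value in the glmnet convention so every path reaches the null model.
The (α, λ) pair minimizing the repeated k-fold cross-validated MSE
(10 folds × 20 repetitions by default) is selected, the model refit on all
data, and importance reported as 100·|β_j|/max|β|. DTH correction, when
requested, regresses DTH out of the response first, mirroring the LSmeans
covariate treatment. Because the CV-MSE surface is nearly flat when no
signal exists, the exact minimizer is unstable under pure noise; the
selected model is nonetheless strongly shrunk toward the null, which is the
property the tests assert.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the package targets: 242 lines (including 3 checks), ~19,353
SNPs (scalable), 4 environments with mean yields 3500/2257/4673/4776
kg ha⁻¹, 12 blocks per environment, and variance components
σ²_G = 200,000, σ²_GE = 100,000, σ²_ε = 400,000 kg² ha⁻², giving a
plot-basis GY heritability of 1/3, inside the observed 0.20–0.41 range.
Block effects are i.i.d. normal with a 200 kg ha⁻¹ SD — a free parameter,
since no adjustment magnitudes are reported for such designs.

Mechanics and deliberate choices:

* Marker MAFs are uniform on (0.05, 0.5]; lines are fully inbred by default
  (configurable residual heterozygosity for exercising the Fisher filter).
* QTL effects are drawn i.i.d. normal on a random marker subset
  (300 by default) and rescaled so the sample variance of g equals σ²_G
  exactly; GE deviations are i.i.d. normal per line×environment
  (exchangeable, reaction-norm-free, matching the Hadamard covariance
  assumption) and rescaled likewise. Exact rescaling makes
  parameter-recovery targets sharp.
* Scalar traits are generated as mean + loading × z + noise, where z is the
  standardized (g + ge) signal of the plot, so a loading is directly the
  trait-unit SD contributed by genetics and target trait–yield correlations
  are computable in closed form (r = loading/√(loading² + noise²) times the
  yield-side dilution √H²). CT's default loading is negative (cooler canopy
  ↔ higher yield). MT is realized through its conductivity pair: T2 is held
  at a baseline and T1 = T2(1 − MT/100).
* NDVI follows a per-plot linear decay over six AGDD stamps
  (100…850 °C·day) with the slope correlated with g at a configurable
  loading plus measurement noise; AGDD_PM = 1000 °C·day puts default SG
  near 0.3–0.45. DTH is drawn around 107 d with configurable genetic
  loading (0 by default, making the DTH covariate orthogonal to yield).
* Everything is reproducible bit-for-bit from the config seed; independent
  substreams are used for markers, trial, physiology and weather.

What the generator does **not** emulate: sequence-level GBS reads, linkage
disequilibrium (markers are independent), spatial field trends, heteroge-
neous residual variances across environments, and selection history in the
panel (population structure is absent unless planted, so the DAPC-stratified
folds on default simulations resemble random folds). Passing tests on this
generator therefore demonstrate correctness of the estimators and the
qualitative behavior of the models under the assumed covariance structures,
not performance on real field data.

## Problem sizes used in the automated studies

The package's own studies (test suite and the reproduction script) run at
deliberately reduced scale, chosen so each check isolates one property:
the BLUP oracle on 40 lines; variance-component recovery on the full
242 × 4 record grid with 2,000 markers and 3,000-iteration chains;
heritability recovery on 300-line single-environment trials;
cross-validation comparisons on 150 lines × 3 environments × 2,000 markers
with 1,500-iteration chains. These sizes give stable Monte-Carlo estimates
of the quantities being checked; all scale parameters are plain function
arguments, and the full-size defaults run the same code paths.

## Known limitations

* Homogeneous residual variance across environments.
* LD-KNNi imputation is out of scope; column-mean/major-allele imputation
  stands in, and any externally imputed matrix is accepted.
* The joint LSmeans model assumes independent block effects within
  environments; no spatial adjustment.
* The DAPC discriminant step is omitted, and k-means with a fixed seed is
  the only clustering offered.
* Whether the elastic-net penalty reported for real data lies on the
  standardized-response scale cannot be determined without that data; all
  penalties here are on the standardized scale.
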