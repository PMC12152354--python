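# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic cohort does and does not emulate, and the
numerical conventions. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Quality control and aggregation

Nuclei are kept when **detected genes > 200**, **total UMIs > 500**, and
**mitochondrial percentage < 5** — all strict inequalities, applied to raw
counts, with the mitochondrial gene set supplied explicitly (by id list or
the `MT-` name-prefix convention), never inferred. Filtering is idempotent
and an all-removed outcome is an error carrying per-criterion failure counts.

Pseudobulk counts are plain sums over (sample, cell type, placental side)
groups; total UMI mass is conserved, and group sizes are recorded. Gene
filtering is **stratum-local**: within each (cell type, side) stratum a gene
needs ≥ 10 summed counts across that stratum's samples, so a gene may survive
in one cell type and be dropped in another.

Normalization is log1p of counts-per-10,000:
`x = ln(1 + 1e4 · c / L)` with `L` the nucleus's UMI sum. It is invariant to
per-nucleus scaling, maps zeros to zeros, and preserves sparsity. Per-nucleus
scoring consumes this matrix; the NB models below consume raw counts with
offsets instead.

## 2. Negative-binomial association engine

One engine serves both association scans:

* **pseudobulk DE**: counts per (sample × gene) within a stratum, predictor
  either the MO-vs-lean group contrast or standardized continuous BMI,
  offset = log total pseudobulk counts per sample;
* **bulk phenotype scan (TWAS-style)**: subject-level counts, predictor a
  standardized child-outcome score, offset = log library size; the signed
  per-gene Wald z from this scan becomes a signature weight.

The model is a log-link NB2 GLM with **fixed per-gene dispersion** α
(variance μ + αμ²), fitted by IRLS (max 50 iterations, relative deviance
tolerance 1e-8, scale fixed at 1). α comes from a method-of-moments
estimator on offset-adjusted counts, `α = max((s² − ȳ)/ȳ², floor)`, clipped
to [1e-8, 10]. This is deliberately simpler than shrinkage-based dispersion
estimation: it is transparent, testable, and adequate for producing a
per-gene signed statistic, at a documented cost in power at small n. Wald
p-values use the normal reference. Non-convergence, separation, or an
unusable standard error yields `converged = False` with missing statistics —
never a fabricated value. Categorical covariates are one-hot encoded with
the lexicographically first level as reference so designs are deterministic;
rank-deficient designs raise an error naming the aliased columns.

Benjamini–Hochberg FDR is applied within each stratum's table, and across
the stratum × program grid for enrichment results.

Default covariates differ by scan. The bulk scan (n = 200 subjects) adjusts
for maternal age, maternal education, delivery mode, fetal sex and batch.
The pseudobulk DE default is maternal age + fetal sex only: with 10 samples
per stratum a full one-hot design for mode and batch leaves almost no
residual degrees of freedom; the full list remains available in the config.

## 3. Footprint scoring (ulm / mlm)

A gene program is a signed weight vector. Activity in a profile **x** is
estimated by ordinary least squares over the genes shared between **x** and
the program:

* **ulm** — one program per regression, `x_g ~ 1 + w_g`; the score is the
  t-value of the slope with df = n − 2;
* **mlm** — all programs jointly, `x_g ~ 1 + W`; score_k is the t-value of
  coefficient k with df = n − K − 1. Collinear programs raise an error
  naming them.

The t-value (rather than the raw slope) is the score because it is
self-normalizing across profiles with different residual noise; under a
fixed gene set it changes scale, not ranks. Below `min_overlap = 5` shared
genes a score is **missing with a recorded reason**, never silently zero —
a two-gene regression has no error degrees of freedom. Perfect fits
(SSR < 1e-12) return signed infinity with p = 0; a slope whose explained sum
of squares is below the same tolerance is reported as exactly 0. Explicit
zero weights in a program participate in the regression; genes absent from
the program do not, so adding unweighted genes to a profile changes nothing.

Per-nucleus scores are descriptive quantities: p-values are computed but not
FDR-corrected by default. Enrichment of a DE statistic vector against
programs (the same regressions with the Wald z vector as the profile) is
corrected across the stratum × program grid.

**Signature derivation** turns an association table into a program: the
min(top_n, available) genes with smallest p (ties broken by larger |stat|,
then gene id — fully deterministic), weighted by the signed statistic.
Raw p is used for selection; BH within one table is monotone in p, so the
selected set is identical either way. Default top_n = 500.

## 4. Correlation and mediation

Activity scores are not guaranteed Gaussian, so correlations pass a
Shapiro–Wilk gate (valid for 3 ≤ n ≤ 5000; callers subsample above that):
p < 0.05 routes to rank-based association. Spearman's rho is Pearson on
average ranks; its p-value uses `t = rho·sqrt((n−2)/(1−rho²))` with n − 2 df;
|rho| = 1 is reported as p = 0 with a perfect-monotone flag. BH-FDR is
applied across an outcome list.

Mediation uses linear structural equations without treatment–mediator
interaction, for continuous treatment t (BMI), mediator m (HGS) and outcome
y (NBIGS):

    m = i₁ + a·t + X·g₁ + e₁
    y = i₂ + c′·t + b·m + X·g₂ + e₂

ACME = a·b, ADE = c′, total = ACME + ADE (an exact identity for nested OLS
models with shared covariates — asserted to 1e-8), proportion mediated =
ACME / total as a point-estimate ratio, flagged undefined when |total| is at
float-noise level. Inference is a seeded nonparametric bootstrap over rows
(default B = 1000) with percentile intervals and two-sided
p = 2·min(P(θ* ≤ 0), P(θ* ≥ 0)) floored at 2/B. A sign-instability flag is
set when any bootstrap total changes sign, since the proportion's ratio CI
is then unreliable. Covariates are optional and empty by default for the
mediation step.

**Unit of analysis.** The default unit is the nucleus, with sample-level BMI
broadcast to nuclei; `unit: sample` aggregates scores to sample medians
first. Nuclei from one placenta share their exposure, so nucleus-level
bootstrap intervals understate sampling uncertainty (pseudoreplication); the
pipeline logs this caveat on every run. The point estimates are unaffected.

## 5. The synthetic cohort

The generator emulates the statistical skeleton of a term-placenta MO
case-control design: 20 samples (half maternal-facing, half fetal-facing;
within each side half lean with BMI uniform on [18.5, 25] and half MO with
BMI uniform on (35, 45]), 500 nuclei per sample, 2000 genes. Each nucleus
of cell type k carries latent activities

    h = h0_k + a_k·z + ε_h,   m = m0_k + b·h + c′·z + ε_m,

with z the standardized sample BMI and unit noise SDs. Cell types
(EVT 20%, SCT 30%, VCT 20%, FB 15%, Endo 15%) differ in their BMI→hypoxia
slope a_k — largest for the EVT-like type (0.8 vs 0.45…0.05) — and in their
activity intercepts (h0, m0 highest in EVT). The intercepts matter: BMI is
centered, so without them every type's median NBI score would be ~0 and no
cell-type ranking could exist; they encode the observation that EVTs express
NBI-associated genes most highly irrespective of exposure. With a_EVT = 0.8,
b = 0.55, c′ = 0.56 the true proportion mediated in EVTs is 0.44 by
construction.

Counts are NB with log-mean `baseline_g + δ_gk + s_h·w_h(g)·h + s_n·w_n(g)·m`,
renormalized per nucleus and scaled by library size. Defaults and rationale:

| parameter | default | rationale |
| --- | --- | --- |
| program sizes | 100 genes each, disjoint | canonical pathway-signature scale; zero overlap keeps score cross-talk a controlled experiment |
| weight scales s_h, s_n | 0.75 | a strong canonical stress-response program: up to ~2-fold expression change per SD of activity for typical weights, so 100-gene scores are informative on a 2000-gene panel |
| baseline log-mean | N(0, 1.2) | a realistic spread of expression levels |
| cell-type expression offsets δ | N(0, 0.3) per (type, gene) | cell identity beyond the two programs |
| dispersion | lognormal(ln 0.5, 0.5), clipped [0.05, 3] | typical snRNA-seq gene-level overdispersion |
| library size | lognormal(ln 1500, 0.3), min 700 | down-scaled depth proportional to the 2000-gene panel |
| mito genes | 13 `MT-` genes at ~1.5% of mass | enough headroom below the 5% QC threshold that only constructed failures fail |
| QC failures | 5% of nuclei | half with <200 detected genes, half with >10% mito — exactly round(fraction × N) nuclei fail, by construction |

The bulk cohort (200 subjects) carries the NBI program only:
`m_s ~ N(0,1)`, expression log-mean `baseline + s_n·w_n·m_s`, outcomes
`y = m_s + noise` (three outcomes at different noise levels). An optional
`bulk_hypoxia_rho` adds a subject-level hypoxia activity correlated with
m_s. Its default is 0 — a deliberate choice: with rho > 0 the phenotype tags
both programs, the derived NBI signature absorbs hypoxia genes, the outcome
score partially measures the mediator, and the estimated mediated proportion
inflates and destabilizes. That contamination is a real transfer-learning
hazard worth studying — as a controlled experiment, not as the default
condition. A consequence of the clean default is that the bulk HGS-vs-
outcome correlation table produced by the pipeline is null-distributed.

One pseudo-random stream per output block (weights, activities, counts,
bulk, covariates, QC) is split from the master seed, so changing the gene
count does not perturb the latent activities, and identical configs are
bit-identical.

**What the simulation does not emulate** — and therefore what passing tests
do not establish about real data: ambient RNA, doublets, batch effects on
expression, cell-type proportion shifts with exposure, confounding between
BMI and covariates, nonlinearity in the structural equations, and
realistic gene–gene correlation beyond the two programs. Recovery results
here certify the machinery, not the biology.

## 6. Numerical conventions and known limitations

* Coefficients are fitted on the natural-log scale and reported as log2 fold
  changes; Wald statistics are scale-free.
* All tie-breaks (signature selection, covariate level ordering, stratum
  ordering) are deterministic; pipeline stages derive child seeds by stable
  hashing of (master seed, stage name), and the manifest records sha256
  hashes of every output for end-to-end determinism checks.
* **Attenuation:** the scored HGS is a noisy measurement of the latent
  hypoxia activity. Measurement error in a mediator biases the b-path, and
  hence the estimated proportion mediated, toward zero; on the default
  cohort the nucleus-level estimate centers a few points below the
  constructed 0.44. The acceptance script therefore reports the mediated
  proportion averaged over replicate cohorts, separating this structural
  estimate from single-cohort sampling noise (10 BMI draws dominate it).
* The mediation model assumes sequential ignorability and no
  treatment–mediator interaction; no sensitivity analysis is provided.
* The NB engine fits each gene independently with moment-based dispersion:
  no shrinkage, no outlier replacement, no per-subject random effects.
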