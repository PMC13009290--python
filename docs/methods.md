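# Methods

`growvar` implements a complete quantitative-genetic analysis of growth
resilience from longitudinal fish weights: allometric growth-curve fitting,
log-variance resilience indicators, a genomic relationship matrix, and
REML variance components under genomic animal models. This note documents
the models, the numerical choices, and what the synthetic-data generator
does and does not emulate.

## Growth model and the weight exponent

Weight at age *t* is modelled as `W_it = a + b_i t^f` with a shared
allometric exponent *f* and per-fish slope `b_i`. Raising weights to `1/f`
linearizes growth, so each fish can be summarized by an ordinary
least-squares line on the transformed scale: its slope is the daily growth
coefficient (DGC, units g^(1/f)/day) and its residuals are the growth
deviations from which the resilience indicator is computed.

Two estimators of *f* are provided:

* **Power-transform profile likelihood** (default). *f* is chosen so that
  per-fish straight lines fit `W^(1/f)` best under a Gaussian model,
  including the Box–Cox Jacobian term `(1/f − 1) Σ ln W` that makes
  likelihoods comparable across exponents. This is the maximum-likelihood
  estimator when growth is linear on the `1/f` scale with additive noise
  there — exactly the working assumption of the deviation analysis — and
  it recovers a generating exponent of 1.77 to within a few hundredths at
  the package's study scale (~850 fish × 5 ages).
* **Observed-scale nonlinear least squares** (`method="observed"`).
  Minimizes `Σ (W − a − b_i t^f)²` with closed-form profiled `a` and
  `b_i`, leaving a smooth one-dimensional objective in *f*. The two curve
  families coincide only when the intercept vanishes; on data that are
  linear on the `1/f` scale with a sizeable intercept this estimator
  systematically attenuates *f* (to ≈1.45 for a generating 1.77 at the
  defaults), which is why it is not the default. It remains exact for data
  truly generated as `a + b_i t^f`.

Both use a coarse grid (step 0.05 over [0.2, 5]) to locate the basin and
flag multimodality, then bounded Brent refinement. A variant profiling a
separate residual variance per fish was considered and rejected: with five
observations and three free quantities per fish it degenerates (the
incidental-parameters problem drives *f* to the boundary).

Known limitation: the profile likelihood assumes a common residual
variance across fish. When the deviation variance is strongly
heterogeneous (the non-aerated configuration, where the log-variance
spread is largest) the estimate acquires a small upward bias (~+0.05);
pooling two ponds with different residual variances behaves similarly.

## Deviations and heteroscedasticity

Deviations of observed from expected weight are computed on three scales:
the `1/f` scale (OLS residuals, which sum to zero per fish by
construction), the observed gram scale, and the cube-root scale
conventional for round-bodied fish. `heteroscedasticity_profile` reports
the per-age mean and SD of deviations plus a max/min SD ratio; on
simulated study-scale data the ratio on the `1/f` scale is far below the
observed-scale ratio, which is the entire point of estimating *f* from the
data. Note that even with perfectly homoscedastic noise the per-age
residual SDs vary through the OLS leverages (`SD_t ∝ √(1−h_t)`), so a
ratio of exactly 1 is not the homoscedastic reference.

Back-transforming to the gram or cube-root scale requires a positive
expected linearized weight. A fish whose fitted line crosses zero at day 1
raises a domain error naming the fish and age in strict mode; the bulk
pipeline path converts such observations to missing with a warning, since
a handful of extreme fish must not abort a 5,000-observation analysis.

## Resilience indicators

**LnVar_ind** is the natural log of the sample variance (n−1 denominator)
of a fish's `1/f`-scale deviations across its measurement ages. The
denominator choice is a monotone shift of the indicator and does not
affect downstream genetic parameters. Variances below 1e−12 are flagged
degenerate and set missing rather than −∞ so mixed models stay well posed.

**LnVar_coh** replaces the individual growth line by the cohort (nursery
hapa × sex × pond) reference: per age, each fish's deviation is
standardized by the cohort SD at that age, and LnVar_coh is the log sample
variance of those standardized deviations. Standardization is a
documented design choice: it makes deviations comparable across ages
despite the growing cohort spread, and it is consistent with indicator
means near −1 rather than the large positive values raw gram deviations
would produce. A raw-deviation mode is available behind
`standardize=False`. Cohort–age cells below a configurable floor
(default 5 fish) yield missing values with a warning.

## Genomic relationship matrix

VanRaden's second method: each marker is centred by twice its in-sample
allele frequency and standardized by `√(2p(1−p))` before averaging, so
every marker contributes equally regardless of frequency. Markers with
MAF < 0.01 (configurable) or zero variance are dropped; missing dosages
are mean-imputed per marker. G is blended with 1% identity to guarantee
positive definiteness for REML — the MAF floor and blend are package
defaults, configurable, since no universal convention exists. Allele
frequencies come from the genotyped sample itself; no base-population
frequencies are assumed. With in-sample frequencies the diagonal averages
≈1 and the off-diagonal average is forced to ≈−1/(n−1), so relationships
are interpreted relative to the sample.

## Animal models and AI-REML

The univariate model is `y = Xβ + a + e` with `a ~ N(0, σ²_A G)` and
`e ~ N(0, σ²_e I)`; fixed effects are an overall mean, nursery hapa
(4 levels) and sex (3 levels) in reference-level coding, plus a
start-weight covariate for harvest weight only. Bivariate models use
additive covariance `C ⊗ G` and residual covariance `R ⊗ I`; for the
cross-environment design (each fish recorded in one pond) the residual
covariance is fixed at zero and the genetic covariance across ponds is the
quantity of interest. Heritability is `σ²_A / (σ²_A + σ²_e)`.

The optimizer is average-information REML on a generic dense
representation `V = Σ θ_i V_i`:

* Newton steps use the AI matrix `0.5 y'P V_i P V_j P y`; step halving
  keeps the restricted log-likelihood non-decreasing across accepted
  iterations, with an EM-flavoured gradient fallback when an AI step
  cannot improve it.
* Steps are taken in working coordinates: **log variances** (positivity
  without corner constraints) and **linear, unconstrained covariances**.
  Only the overall V must stay positive definite (a failed Cholesky
  rejects the step). Constraining each covariance to an implied
  correlation inside [−1, 1] was tried first and rejected: weakly
  identified correlations pile up on the boundary (about 20% of
  cross-environment replicates at the default signal level), which biases
  Monte-Carlo means; leaving the covariance free is how
  unstructured-covariance REML software behaves. Reported correlations
  are clipped to [−1, 1] with a boundary flag; the raw estimate is kept
  as `r_g_raw`.
* Convergence: relative log-likelihood change < 1e−8 and relative
  parameter change < 1e−6, at most 200 iterations. Typical fits converge
  in 5–15 iterations.
* Standard errors of heritabilities and correlations come from the delta
  method on the inverse AI matrix, mirroring the reporting convention of
  standard REML software. The SE of h² is suppressed when σ²_A sits on
  its floor.
* Breeding values are BLUPs `Cov(a, y) V⁻¹ (y − Xβ̂)` at the converged
  components, with accuracies from prediction-error variances. In the
  cross-environment model every animal gets an EBV in both ponds, the
  unobserved pond's through the genetic covariance.

All dense algebra runs through LAPACK Cholesky routines (`dpotrf` /
`dpotri`); a bivariate fit on 1,600 observations costs a few hundred
milliseconds per iteration on one core, so no structured factorization is
needed at this scale.

## Synthetic data generator

The generator inverts the analysis: growth is linear on the `1/f` scale,
`L_it = a_i + b_i t + e_it`, `W_it = L_it^f`, with

* intercept `a_i` = 8.3 g^(1/f) plus hapa and sex shifts (back-solved
  from the published harvest-weight and DGC means: e.g. 781 g^(1/1.77) −
  0.16 × 217 ≈ 8.4),
* slope `b_i` = pond mean DGC (0.16 / 0.13 g^(1/1.77)/day) + breeding
  value + environmental deviate,
* heteroscedastic noise `e_it ~ N(0, exp(η_i))` whose log-variance
  `η_i` = pond baseline + breeding value + environmental deviate.

Because LnVar_ind is the log of a variance *estimated* from five
deviations, its phenotypic moments differ from η's by known constants:
`E[LnVar] ≈ E[η] − 0.657` and `Var[LnVar] ≈ Var[η] + 0.935` (mean and
variance of `ln(χ²₃/ (n−1))`). The default baselines (1.99 / 1.69) and
environmental variances of η (0.062 / 0.188) are back-solved from the
published indicator means and phenotypic variances using these constants;
the slope's environmental variances (0.38e−3 / 0.175e−3) likewise subtract
the OLS slope sampling noise `exp(baseline)/Σ(t−t̄)²` from the published
DGC phenotypic variance. Additive variances are the published ones.

Breeding values for (slope, log-variance) × (pond) form a 4-trait system
with correlation matrix defaults taken from the published within-pond
(−0.44 / −0.68) and cross-pond LnVar (0.50) correlations; the cross-pond
slope correlation (0.75) and the cross trait-pond terms (−0.30) are not
published anywhere and were fixed once as plausible values verified
positive semi-definite. BVs are sampled by gene-dropping on the pedigree
(founders `N(0, C)`, offspring mid-parent plus `N(0, C/2)`), so their
covariance matches the genomic relationships in expectation.

The mating design is a simplification of mass spawning: sires and dams
split evenly over 4 hapas, dams nested within sires, offspring allocated
to dams multinomially (a Dirichlet knob adds family-size imbalance), and
fish randomly allocated to the two ponds so families span environments.
Genotypes are gene-dropped per SNP from parental `Binomial(2, p)` draws
with `p ~ U(0.05, 0.5)`. The default marker count is 3,000 for desk-scale
work; the recovery experiments use 11,293, the marker count behind the
study-scale relationship matrix, which noticeably sharpens weakly
identified cross-environment correlations. Positivity of linearized
weights is enforced by resampling deviations (capped at 100 tries, then
an error naming the fish), which avoids the variance bias truncation
would introduce. Missing harvest records are missing-at-random drops;
the stocking record is never dropped. The fraction of unknown-sex fish is
configurable (default 5%) since no mechanism is published.

What the generator does **not** emulate: dissolved-oxygen dynamics,
feeding, mortality or tagging loss; genotyping error or missingness
patterns of GBS data; selection history. Passing recovery tests therefore
show that the estimation machinery is consistent under the package's own
generative assumptions at realistic sample sizes — not that real pond
data satisfy those assumptions.

## Problem sizes and reproducibility

Recovery experiments run at the study's scale: ~850 fish for the
exponent, n = 800 per pond for variance components, 20 replicates for
means of heritabilities and correlations (10 for the exponent and the
DGC–W5 correlation). Monte-Carlo standard errors of the reported means
are ~0.015 for h² and ~0.03–0.07 for genetic correlations. All
randomness derives from one integer seed via `SeedSequence` spawning;
rerunning any experiment or the full pipeline with the same seed
reproduces every number bit for bit.

Estimated correlations with |r| near 1 (the DGC–W5 pair, and occasional
cross-environment replicates) are reported clipped with a boundary flag.
The cross-environment genetic correlation is intrinsically noisy at the
study's signal level (per-replicate SE ≈ 0.3, matching the published
standard error): single estimates should be read with that in mind.

Correlation-recovery experiments are summarized by the **pooled**
correlation `mean(ĉov_A) / √(mean(σ̂²_A1) · mean(σ̂²_A2))` rather than the
mean of per-replicate ratios. The ratio's noisy square-root denominator
makes its distribution strongly right-skewed when one additive variance is
weakly identified (h² ≈ 0.06): across 20-replicate batches the clipped
mean-of-ratios sits 0.05–0.10 above a generating correlation of 0.50,
with 15–20% of fits at the |r| = 1 boundary (verified as genuine REML
optima by profile-likelihood checks), while the pooled components are
nearly unbiased. The per-replicate estimates are returned alongside the
components, so either summary can be formed.
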