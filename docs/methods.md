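# Methods

`svdrisk` re-implements, as a tested pipeline over synthetic data, a
latent-variable analysis of how modifiable midlife dementia risk relates to
cerebral small vessel disease (SVD) burden in a cognitively healthy cohort
aged 40–59, including the moderating role of APOE ε4.  This note documents
the models, the choices made where the design was genuinely open, and what
the synthetic data do and do not show.

## Composite SVD scores

Visual ratings per subject: periventricular and deep Fazekas grades (0–3),
EPVS severity bins (0–4, basal ganglia and centrum semiovale; a count of
0 / 1–10 / 11–20 / 21–40 / >40 maps to 0–4), and presence flags for
definite microbleeds and lacunes by deep vs lobar location.  Three 0–4
composites award one point per criterion met:

| criterion | global SVD | CAA | hypertensive arteriopathy |
|---|---|---|---|
| lacunes | any | ≥1 lobar | ≥1 deep |
| microbleeds | any | ≥1 lobar | ≥1 deep |
| EPVS | basal ganglia ≥ 2 | centrum semiovale ≥ 2 | basal ganglia ≥ 2 |
| WMH | PV Fazekas = 3 or deep ≥ 2 | PV Fazekas = 3 or deep ≥ 2 | deep Fazekas ≥ 2 |

The global rule is the published Staals rule; because published variants of
the global WMH criterion exist, the rules are data (ordered criterion
tables in `svdrisk.scoring`) and can be swapped without touching the
scoring machinery.  Any missing constituent rating blanks all three scores
for that subject (no partial credit).

## Modifiable risk score

Six early/midlife risk factors are dichotomised exactly at the published
cut-offs: education < 13 years, self-reported hearing loss, head injury
with loss of consciousness, alcohol > 21 units/week, SBP ≥ 140 or
DBP ≥ 90 mmHg, waist-to-hip ratio ≥ 0.78 (F) / ≥ 0.87 (M).  The composite
score weights hypertension and obesity 2 points each (strongest loadings on
the latent risk construct) and the rest 1, range 0–8.  Missing inputs yield
missing flags — never an implicit 0 — and any missing flag blanks the
composite; imputing absent risk would bias the score downward, and the SEM
side handles missingness by FIML anyway.

## WMH volumetrics

Lesion voxels are brain-mask voxels with intensity strictly greater than
1.2 × the median intensity over the brain mask (scale-invariant by
construction; the strict inequality resolves ties at exactly 1.2×).  The
periventricular/deep split replaces atlas-space mask dilation with a direct
Euclidean distance transform in subject space (voxel spacing respected),
default boundary 10 mm — the effective distance the dilation approach
targets — with a 6-connected iterative-dilation mode retained for fidelity
experiments.  Volumes are voxel count × voxel volume; WMH burden is
reported as (WMH/TIV)·100 and its cube root (the percent scale is strongly
right-skewed).  Manual editing of lesion maps by a rater is not modelled.
A phantom generator (ellipsoidal brain, central ventricular box, spherical
lesions at 2× background) provides voxel-exact ground truth.

## SEM engine

Models are written in a compact `=~` / `~` / `~~` text syntax and held in
RAM form: v = Av + u, Cov(u) = S, Σ = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ (plus
μ = F(I−A)⁻¹m under a mean structure).

* **Estimation.** Covariance ML minimises
  F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p; FIML maximises the casewise Gaussian
  log-likelihood over each case's observed variables, grouped by
  missingness pattern; the FIML objective is scaled per case so gradient
  tolerances are size-independent.  Gradients are analytic (rank-two RAM
  derivative identities); variance parameters are optimised on the log
  scale; L-BFGS-B with gradient tolerance 1e-8 and up to 10 random
  restarts; non-convergence raises, never passes silently.
* **Conventions.** χ² = (n−1)·F at the optimum for covariance ML (sample
  covariance with divisor n−1); under FIML, χ² = 2(ℓ_sat − ℓ_model) with
  the saturated model estimated by EM.  Baseline for CFI is the
  independence model (free variances, plus free means under FIML); for
  complete data its χ² has the closed form −(n−1)·ln|R|.
  RMSEA = √(max(χ²−df,0)/(df·(n−1))), SRMR is the RMS standardised
  covariance residual (lower triangle including the diagonal; under FIML
  the EM-saturated covariance plays the sample's role).  Standard errors
  come from the inverse observed information (numerically differentiated
  analytic gradient).
* **Identification.** Default is marker identification (first loading fixed
  to 1); `std_lv` fixes latent variances instead.  The standardised
  solution is reported regardless, so results do not depend on the marker
  choice — except for sign: the pipeline anchors latent RISK on systolic
  BP because the alphabetically/theoretically first indicator (education)
  loads negatively and would flip the latent's direction.
* **Modification indices** are univariate score (Lagrange-multiplier)
  statistics for freeing one fixed edge, using the expected (Fisher)
  information with a Schur complement for the nuisance block.  The observed
  information was tried first and proved indefinite along cross-loading
  directions involving marker indicators; the expected information is the
  conventional choice and agrees with explicit refit Δχ² within ~10% in
  the checks.  The re-specification threshold 3.84 is the χ²(1) 0.95
  quantile.
* **Binary indicators** (microbleed/lacune presence, hearing loss, TBI) are
  treated as numeric under ML, mirroring the estimator choice the analysis
  emulates; categorical limited-information estimators (WLSMV etc.) are out
  of scope, so loadings for those indicators are attenuated relative to a
  threshold-model view.
* **Interaction.** Latent-by-latent products are not estimable here, so the
  APOE4 moderation model regresses latent SVD on the observed composite
  risk score, APOE4, their product, age and sex, all predictors mean-
  centred before the product is formed.
* **Trimming and FDR.** The structural model starts with APOE4 and sex
  paths into both latents; trimmable paths (APOE4→SVD, APOE4→RISK,
  SEX→SVD) are removed one per step, largest Wald p first, while p ≥ 0.05.
  Benjamini–Hochberg FDR is applied across the structural-path p-values of
  the final model (the FDR scope is the structural coefficients; the
  measurement loadings are not part of the correction).

No established SEM package ships in this environment, so the test suite
carries an independently coded brute-force fitter (reduced-form covariance
propagation, finite-difference L-BFGS-B) as a second route; the two agree
to 1e-3 relative on randomised small models.

## Classical statistics

Spearman correlations use midranks with a t-approximate p-value (adequate
at cohort n; exact permutation is available for n ≤ 8).  Adjusted models
are OLS or binomial GLMs via statsmodels, always adjusting for sex
(0 = female, 1 = male), age centred at the sample mean, and study site
dummy-coded against site 1 (reference level unspecified in the source
design; first site is this package's documented choice).  All predictors
are mean-centred; two-sided p-values, α = 0.05.  Perfect separation and
rank deficiency are detected and raised, not smoothed over.  Cohen's kappa
comes from the k×k agreement table formula (p_o − p_e)/(1 − p_e).

## Synthetic cohort generator

The generator is the study-conditions module: its defaults *are* the
emulated cohort (n = 630; 61.6% female; age 51.2 (5.5) in [40,59]; APOE4
38.4%; family history 53.3% with an APOE4 enrichment odds ratio of 2;
education 16.7 (3.4) y; hypertension 16.5%; obesity 26.2%; high alcohol
14.1%; hearing loss 10.8%; TBI 35.4%; microbleeds 16.8%; lacunes 10.5%;
WMH 0.13% of TIV; latent Risk→SVD path 0.80; APOE4×risk interaction
−0.31).  Mechanics:

* Latents: RISK = 0.25·z_age + 0.10·z_sex + ζ; SVD = 0.80·RISK +
  0.20·z_age − 0.31·(APOE4−p̄)·RISK + ζ, both scaled to unit variance.
* Indicators: standard-normal propensities X = λ·latent + √(1−λ²)·ε with
  default standardised loadings (sbp .65, whr .60, education −.45, alcohol
  .35, hearing .35, tbi .30; wmh .70, epvs_bg .55, cmb .45, lacunes .45).
  Continuous measures are affine maps of their propensity into natural
  units; binaries threshold the propensity at the normal quantile of the
  target marginal (probit link); EPVS and Fazekas grades bin a propensity
  at quantiles of configured category probabilities.
* Blood pressure: SBP is anchored so that P(SBP ≥ 140) equals the
  hypertension target exactly; DBP = 0.55·SBP + noise, so DBP ≥ 90 only
  occurs when SBP ≥ 140 already holds — the hypertension marginal stays
  exactly calibrated and SBP > DBP always.
* Age: a truncated normal on [40,59] cannot reach SD 5.5 (the uniform
  limit is 5.48), so the parent parameters are least-squares fitted and
  age is standardised by the achieved truncated moments (SD ≈ 5.2).
* With the interaction on, the SVD-side propensities are unit-variance
  scale mixtures of normals rather than exactly Gaussian; binary marginals
  shift by < 0.5%, inside the ±2% calibration tolerance.
* Missingness is injected MCAR per column (defaults match the emulated
  missing counts: education 1/630, APOE 5/630, WMH 3/630, CMB 24/630).
  MCAR is a strict subset of the MAR assumption FIML needs, which is
  sufficient for testing FIML correctness.
* Site is multinomial with equal default weights (per-site sizes are not
  specified by the emulated design and are configurable, not claimed).

What the generator does *not* emulate: rating noise and inter-rater
disagreement (one rating per subject), non-Gaussian measurement error,
MNAR missingness, site effects on any variable, and the ordinal character
of the indicators as the fitted model sees them (the SEM treats them as
numeric, exactly as the emulated analysis does).  Passing tests therefore
demonstrate correctness of the machinery under the stated generating
process — not robustness of the scientific conclusion to violations of it.

## Problem sizes and numerical choices

Monte-Carlo checks use 200 replicates at n = 630 for path recovery
(mean standardised estimate within ±0.05 of 0.80; 95% CI coverage within
[0.92, 0.98]) and for interaction sign recovery; FIML unbiasedness under
10% MCAR uses a compact 2-factor, 6-indicator model at n = 300 × 200
replicates — sizes chosen so the whole suite runs in about a minute on one
CPU while keeping Monte-Carlo error well below the tolerances tested.
Continuous SEM indicators are z-scaled inside the pipeline before fitting
(standardised coefficients are scale-free; raw variances spanning four
orders of magnitude merely slow the optimiser).  The CFA→SEM gate passes
at CFI ≥ 0.95 (RMSEA, SRMR ≤ 0.10), proceeds with a warning from
CFI ≥ 0.90, and otherwise skips the structural stages unless forced.

## Known limitations

* ML treats ordinal/binary indicators as numeric; loadings for rare binary
  markers are attenuated (by roughly φ(τ)/√(p(1−p)) under the probit
  generating process), which the recovery tests account for by simulating
  the fitted topology directly where the criterion concerns the SEM
  machinery itself.
* The sex-specific WHR cut-offs make WHR strongly sex-dependent in natural
  units, which surfaces as a large sex→RISK path on synthetic data; the
  sex paths therefore tend to survive trimming even when the generating
  direct effects are small.
* No robust (Satorra–Bentler) corrections, multi-group models, Bayesian
  estimation, or latent-by-latent interactions.
* The WMH module consumes intensity volumes with given masks; tissue
  segmentation, registration and Fazekas rating from images are out of
  scope.
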