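# svdrisk

Latent-variable modelling of modifiable midlife dementia risk and cerebral
small vessel disease (SVD) burden.

Cerebral small vessel disease — visible on MRI as white matter
hyperintensities (WMH), enlarged perivascular spaces (EPVS), microbleeds
and lacunes — begins decades before dementia, and much midlife dementia
risk is modifiable (education, hearing, head injury, alcohol, blood
pressure, adiposity).  Because both constructs are multifactorial and each
marker is noisy, single-marker regressions understate their association.
This package implements the full analytic chain for studying the question
at cohort scale with structural equation modelling, for epidemiologists and
neuroimaging researchers who want the pipeline reusable and testable
without access to participant data:

* **`svdrisk.scoring`** — composite SVD scores (global burden, cerebral
  amyloid angiopathy subtype, hypertensive arteriopathy subtype; each 0–4,
  one point per marker-class criterion) from visual ratings.
* **`svdrisk.risk`** — the six early/midlife risk factors dichotomised at
  published cut-offs and the weighted composite risk score (hypertension
  and obesity count double; range 0–8).
* **`svdrisk.wmh`** — threshold-based WMH segmentation (>1.2× median brain
  intensity), periventricular/deep split at a 10 mm boundary, volumes as %
  of intracranial volume with cube-root transform; phantom generator for
  ground-truth validation; NIfTI I/O.
* **`svdrisk.semlib`** — CFA/SEM by maximum likelihood in RAM form
  (Σ = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ), full-information ML under missingness,
  CFI/RMSEA/SRMR, score-test modification indices, standardised solutions,
  Wald path trimming, and the observed-moderator interaction model
  (latent SVD ~ risk score × APOE4 + covariates).
* **`svdrisk.statsuite`** — Spearman correlations, covariate-adjusted
  linear/logistic models (sex, centred age, site dummies),
  Benjamini–Hochberg FDR, Cohen's kappa.
* **`svdrisk.cohort`** — a seeded synthetic cohort generator with the
  two-latent-factor structure the analysis assumes, calibrated to the
  emulated study's sample characteristics.
* **`svdrisk.pipeline`** — the end-to-end run: cohort → scores → CFA →
  good-fit gate → structural SEM (trimmed, FDR-corrected) → interaction
  SEM → GLM/Spearman sensitivity analyses → report bundle.

The model at the core: latent RISK (measured by education, systolic BP,
waist-to-hip ratio, alcohol, hearing loss, TBI) and latent SVD (measured by
WMH volume, basal-ganglia EPVS, microbleed and lacune presence), with

    SVD ~ β·RISK + age (+ sex),   RISK ~ age + sex,

fitted by ML/FIML; model fit is judged by CFI (≥0.95 good), RMSEA and SRMR
(<0.05 good, <0.10 acceptable); moderation is tested by adding the
mean-centred APOE4 × risk-score product as a predictor of latent SVD.

## Worked example

The numbered drivers under `analysis/` run the study end to end on a
synthetic cohort (each writes its tables under `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/04_run_pipeline.py
```

The pipeline run prints, among other things:

```
[gate] risk: CFI=0.9970 RMSEA=0.0109 SRMR=0.0235 -> pass
[gate] svd: CFI=1.0000 RMSEA=0.0000 SRMR=0.0125 -> pass
[trim] dropped SVD~apoe4 (p = 0.2475)
[trim] dropped RISK~apoe4 (p = 0.0675)
[structural] SVD~RISK: beta=1.005 p=0.0000, SVD~age: beta=0.268 p=0.0000, ...
[interaction] beta=-0.104 p=0.0205
[sensitivity] interaction GLM on HA: t=-3.198 p=0.0015
```

Reading this: both measurement models fit well, so the gate opens; the two
APOE4 paths are non-significant and trimmed; the latent Risk→SVD
association is positive and significant (the cohort was generated with a
standardised path of 0.80 — the standardised estimate on one n = 630 draw
can exceed it); and the APOE4 × risk interaction on latent SVD is negative
(risk bites harder in non-carriers), echoed by the sensitivity GLM on the
hypertensive-arteriopathy composite.  `analysis/05_recovery_and_power.py`
repeats the simulation 50 times and reports a mean standardised path of
0.801 (SD 0.041) with 94% CI coverage, a 100% negative-sign rate for the
interaction generated at −0.31, and uniform null interaction p-values
(KS p = 0.50).

A command-line entry point wraps the same library:

```bash
svdrisk simulate --n 630 --seed 0 --out cohort.csv
svdrisk run --input cohort.csv --seed 0 --out report/
svdrisk wmh-segment --in flair.nii.gz --brain-mask brain.nii.gz \
    --vent-mask vent.nii.gz --boundary-mm 10
```

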