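"""Observed-moderator interaction on a latent outcome.

Latent-by-latent interactions are not estimable in plain ML SEM, so the
moderation of the risk-SVD association by APOE4 is tested with an observed
composite risk score: the latent SVD variable is regressed on the risk
score, APOE4, their product, age and sex, with every predictor mean-centred
before the product is formed (reduces collinearity between the product and
its components).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import SemFit, SemFitError, fit_fiml, fit_ml
from .model import ModelSpec

__all__ = ["fit_interaction_model", "simulate_interaction_cohort", "INTERACTION_TERM"]

INTERACTION_TERM = "risk_x_apoe4"

DEFAULT_INDICATORS = ("wmh_cuberoot", "epvs_bg", "cmb_any", "lacune_any")


def simulate_interaction_cohort(
    n: int,
    interaction: float = -0.31,
    risk_effect: float = 0.30,
    apoe4_effect: float = 0.05,
    age_effect: float = 0.20,
    sex_effect: float = 0.0,
    p_apoe4: float = 0.384,
    loadings: tuple[float, ...] = (0.70, 0.55, 0.45, 0.45),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Generate data from the observed-moderator interaction model.

    Latent SVD = b_r * risk + b_a * apoe4_c + w * (apoe4_c x risk) +
    b_age * age + b_sex * sex + residual, with risk/age standard normal,
    sex Bernoulli(0.5) and APOE4 Bernoulli(p) (both mean-centred in the
    structural equation), SVD scaled to unit variance, and four continuous
    indicators at the given standardised loadings.  Coefficients are on the
    standardised scale; the default interaction of -0.31 is the cohort
    moderation effect this package emulates.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    risk = rng.standard_normal(n)
    apoe4 = (rng.random(n) < p_apoe4).astype(int)
    apoe4_c = apoe4 - p_apoe4
    sex = (rng.random(n) < 0.5).astype(int)
    sex_c = (sex - 0.5) / 0.5
    age = rng.standard_normal(n)
    var_apoe = p_apoe4 * (1 - p_apoe4)
    resid = 1.0 - (
        risk_effect**2
        + apoe4_effect**2 * var_apoe
        + interaction**2 * var_apoe
        + age_effect**2
        + sex_effect**2
    )
    if resid <= 0:
        raise ValueError("coefficients imply non-positive residual variance")
    svd = (
        risk_effect * risk
        + apoe4_effect * apoe4_c
        + interaction * apoe4_c * risk
        + age_effect * age
        + sex_effect * sex_c
        + np.sqrt(resid) * rng.standard_normal(n)
    )
    out = pd.DataFrame(
        {"risk_score": risk, "apoe4": apoe4, "age": age, "sex": sex}
    )
    for name, lam in zip(DEFAULT_INDICATORS, loadings):
        out[name] = lam * svd + np.sqrt(1.0 - lam * lam) * rng.standard_normal(n)
    return out


def fit_interaction_model(
    cohort: pd.DataFrame,
    risk_col: str = "risk_score",
    apoe4_col: str = "apoe4",
    indicators: tuple[str, ...] = DEFAULT_INDICATORS,
    covariates: tuple[str, ...] = ("age", "sex"),
    seed: int = 0,
) -> SemFit:
    """Fit the APOE4-by-risk moderation SEM on the latent SVD outcome.

    The coefficient of interest is ``SVD~risk_x_apoe4`` in the returned
    fit.  Complete data are fitted by covariance ML; any missingness routes
    through FIML.  Raises if the moderator is constant (the product term
    would be collinear and the model unidentified).
    """
    cols = [risk_col, apoe4_col, *covariates, *indicators]
    missing = set(cols) - set(cohort.columns)
    if missing:
        raise SemFitError(f"cohort lacks columns {sorted(missing)}")
    df = cohort[cols].copy()
    if df[apoe4_col].dropna().nunique() < 2:
        raise SemFitError(
            f"moderator {apoe4_col!r} is constant in the sample; "
            "the interaction model is not identified"
        )
    centred = {}
    for c in (risk_col, apoe4_col, *covariates):
        centred[c + "_c"] = df[c] - df[c].mean()
    work = pd.DataFrame(centred, index=df.index)
    work[INTERACTION_TERM] = work[risk_col + "_c"] * work[apoe4_col + "_c"]
    for ind in indicators:
        work[ind] = df[ind].astype(float)

    predictors = [risk_col + "_c", apoe4_col + "_c", INTERACTION_TERM] + [
        c + "_c" for c in covariates
    ]
    text = "SVD =~ " + " + ".join(indicators) + "\n"
    text += "SVD ~ " + " + ".join(predictors) + "\n"
    complete = work.notna().all(axis=None)
    spec = ModelSpec.from_text(text, meanstructure=not complete)
    if complete:
        S = work[spec.observed_vars].cov(ddof=1)
        return fit_ml(S, len(work), spec, seed=seed)
    return fit_fiml(work, spec, seed=seed)
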