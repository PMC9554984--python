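"""Synthetic midlife cohort generator with a two-latent-factor structure.

Emulates the data structure of a middle-aged (40-59 y) dementia-prevention
cohort enriched for family history of dementia: demographics, APOE4 and
family-history flags, six modifiable risk measurements, visual SVD ratings
and quantitative WMH volume.  Data are drawn from a linear latent-variable
model:

    RISK = g_age * z_age + g_sex * z_sex + zeta_R
    SVD  = b * RISK + c * z_age + w * (APOE4 - p) * RISK + zeta_S

with both latents scaled to unit variance.  Each indicator has a
standard-normal propensity ``X = lam * latent + sqrt(1 - lam^2) * eps``;
continuous indicators are affine transforms of their propensity into
natural units, binary indicators threshold the propensity at the normal
quantile matching the target marginal (probit link), and ordinal ratings
(EPVS, Fazekas) bin a propensity at quantiles of configured category
probabilities.  This is the standard factor-analytic generating process
consistent with maximum-likelihood covariance fitting downstream.

Default marginals reproduce the cohort's printed sample characteristics
(61.6% female, age 51.2 (SD 5.5), APOE4 38.4%, hypertension 16.5%,
obesity 26.2%, lacunes 10.5%, CMB 16.8%, mean WMH 0.13% of TIV, ...);
the latent Risk->SVD path defaults to 0.80 and the APOE4-by-risk
interaction to -0.31 on the standardised scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

__all__ = [
    "GeneratorConfig",
    "CohortConfigError",
    "generate_cohort",
    "inject_missingness",
    "implied_propensity_corr",
    "PROPENSITY_COLUMNS",
    "COLUMN_DICTIONARY",
]


class CohortConfigError(ValueError):
    """Invalid generator configuration."""


#: indicator propensities, in model order (6 risk + 4 SVD + EPVS-CSO extra)
PROPENSITY_COLUMNS = (
    "education",
    "sbp",
    "whr",
    "alcohol",
    "hearing_loss",
    "tbi",
    "wmh",
    "epvs_bg",
    "cmb",
    "lacunes",
)

COLUMN_DICTIONARY = {
    "subject_id": "opaque subject identifier",
    "sex": "0 = female, 1 = male",
    "age": "age in years (40-59)",
    "site": "study site, categorical 1-5",
    "apoe4": "APOE epsilon-4 carrier (0/1)",
    "family_history": "parental family history of dementia (0/1)",
    "education": "years of education",
    "sbp": "systolic blood pressure, mmHg",
    "dbp": "diastolic blood pressure, mmHg",
    "whr": "waist-to-hip ratio",
    "alcohol": "alcohol intake, units/week",
    "hearing_loss": "self-reported hearing impairment (0/1)",
    "tbi": "head injury with loss of consciousness, ever (0/1)",
    "pv_fazekas": "periventricular Fazekas WMH grade (0-3)",
    "deep_fazekas": "deep Fazekas WMH grade (0-3)",
    "epvs_bg": "EPVS severity bin, basal ganglia (0-4)",
    "epvs_cso": "EPVS severity bin, centrum semiovale (0-4)",
    "cmb_deep": "definite deep microbleed present (0/1)",
    "cmb_lobar": "definite lobar microbleed present (0/1)",
    "cmb_any": "any definite microbleed present (0/1)",
    "lacune_deep": "deep lacune present (0/1)",
    "lacune_lobar": "lobar lacune present (0/1)",
    "lacune_any": "any lacune present (0/1)",
    "wmh_pct_tiv": "WMH volume as % of total intracranial volume",
    "wmh_cuberoot": "cube root of wmh_pct_tiv",
}


@dataclass
class GeneratorConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_subjects: int = 630
    seed: int = 0

    # structural part (standardised scale)
    latent_path_risk_to_svd: float = 0.80
    interaction_apoe4: float = -0.31
    risk_on_age: float = 0.25
    risk_on_sex: float = 0.10
    svd_on_age: float = 0.20

    # measurement part: standardised loadings, keyed like PROPENSITY_COLUMNS
    loadings_risk: dict[str, float] = field(
        default_factory=lambda: {
            "education": -0.45,
            "sbp": 0.65,
            "whr": 0.60,
            "alcohol": 0.35,
            "hearing_loss": 0.35,
            "tbi": 0.30,
        }
    )
    loadings_svd: dict[str, float] = field(
        default_factory=lambda: {
            "wmh": 0.70,
            "epvs_bg": 0.55,
            "cmb": 0.45,
            "lacunes": 0.45,
        }
    )
    loading_epvs_cso: float = 0.45  # extra SVD indicator outside the CFA four

    # marginal targets
    p_female: float = 0.616
    age_mean: float = 51.2
    age_sd: float = 5.5
    age_range: tuple[float, float] = (40.0, 59.0)
    p_apoe4: float = 0.384
    p_family_history: float = 0.533
    fh_apoe4_odds_ratio: float = 2.0
    education_mean: float = 16.7
    education_sd: float = 3.4
    p_hypertension: float = 0.165
    p_obesity: float = 0.262
    p_high_alcohol: float = 0.141
    p_hearing_loss: float = 0.108
    p_tbi: float = 0.354
    p_cmb: float = 0.168
    p_lacune: float = 0.105
    wmh_cuberoot_mean: float = 0.46
    wmh_cuberoot_sd: float = 0.16
    epvs_bg_probs: tuple[float, ...] = (0.18, 0.70, 0.10, 0.015, 0.005)
    epvs_cso_probs: tuple[float, ...] = (0.25, 0.63, 0.10, 0.015, 0.005)
    pv_fazekas_probs: tuple[float, ...] = (0.45, 0.45, 0.08, 0.02)
    deep_fazekas_probs: tuple[float, ...] = (0.35, 0.55, 0.08, 0.02)
    # conditional location mix given a lesion is present
    p_cmb_lobar_given_any: float = 0.75
    p_cmb_deep_given_any: float = 0.35
    p_lacune_deep_given_any: float = 0.55
    p_lacune_lobar_given_any: float = 0.45
    site_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)

    # blood-pressure / measurement-unit mapping
    sbp_sd: float = 14.0
    whr_sd: float = 0.06
    alcohol_sd: float = 9.0

    # per-column MCAR missingness (matches the study's printed missing counts)
    missingness: dict[str, float] = field(
        default_factory=lambda: {
            "education": 1 / 630,
            "apoe4": 5 / 630,
            "wmh_pct_tiv": 3 / 630,
            "cmb_deep": 24 / 630,
            "cmb_lobar": 24 / 630,
        }
    )

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise CohortConfigError("n_subjects must be >= 1")
        props = {
            "p_female": self.p_female,
            "p_apoe4": self.p_apoe4,
            "p_family_history": self.p_family_history,
            "p_hypertension": self.p_hypertension,
            "p_obesity": self.p_obesity,
            "p_high_alcohol": self.p_high_alcohol,
            "p_hearing_loss": self.p_hearing_loss,
            "p_tbi": self.p_tbi,
            "p_cmb": self.p_cmb,
            "p_lacune": self.p_lacune,
        }
        for k, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(f"{k}={v} outside [0, 1]")
        for name, lam in self.all_loadings().items():
            if not -1.0 < lam < 1.0:
                raise CohortConfigError(f"loading {name}={lam} outside (-1, 1)")
        for probs in (
            self.epvs_bg_probs,
            self.epvs_cso_probs,
            self.pv_fazekas_probs,
            self.deep_fazekas_probs,
            self.site_weights,
        ):
            if min(probs) < 0 or abs(sum(probs) - 1.0) > 1e-8:
                raise CohortConfigError(f"category probabilities {probs} invalid")
        for rate in self.missingness.values():
            if not 0.0 <= rate <= 1.0:
                raise CohortConfigError(f"missingness rate {rate} outside [0, 1]")
        if self._risk_resid_var() <= 0 or self._svd_resid_var() <= 0:
            raise CohortConfigError(
                "structural coefficients imply a non-positive-definite "
                "latent covariance (residual variance <= 0)"
            )

    def all_loadings(self) -> dict[str, float]:
        out = dict(self.loadings_risk)
        out.update(self.loadings_svd)
        out["epvs_cso"] = self.loading_epvs_cso
        return out

    def _risk_resid_var(self) -> float:
        return 1.0 - self.risk_on_age**2 - self.risk_on_sex**2

    def _svd_resid_var(self) -> float:
        b, c, w = self.latent_path_risk_to_svd, self.svd_on_age, self.interaction_apoe4
        var_apoe = self.p_apoe4 * (1 - self.p_apoe4)
        return 1.0 - (b**2 + c**2 + 2 * b * c * self.risk_on_age + w**2 * var_apoe)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["age_range"] = list(d["age_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in (
            "age_range",
            "epvs_bg_probs",
            "epvs_cso_probs",
            "pv_fazekas_probs",
            "deep_fazekas_probs",
            "site_weights",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _truncnorm_parent_params(mean: float, sd: float, lo: float, hi: float):
    """Parent (mu, sigma) of a truncated normal best matching target moments.

    Truncation shrinks the realised SD, so the parent SD must exceed the
    target; a target SD near the interval's uniform limit (width/sqrt(12))
    may be unattainable, in which case the least-squares best fit is used.
    Returns (mu, sigma, achieved_mean, achieved_sd).
    """

    def resid(x):
        mu, log_sigma = x
        sigma = np.exp(np.clip(log_sigma, -5.0, 8.0))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.least_squares(resid, x0=[mean, np.log(sd * 1.5)], xtol=1e-12)
    mu, sigma = float(sol.x[0]), float(np.exp(np.clip(sol.x[1], -5.0, 8.0)))
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    d = stats.truncnorm(a, b, loc=mu, scale=sigma)
    return mu, sigma, float(d.mean()), float(d.std())


def _fh_apoe4_joint(p_a: float, p_f: float, odds_ratio: float) -> float:
    """P(APOE4=1, FH=1) for given marginals and odds ratio (enrichment)."""
    if abs(odds_ratio - 1.0) < 1e-12:
        return p_a * p_f
    r = odds_ratio
    # r = p11*p00 / (p10*p01), with margins fixed -> quadratic in p11
    a = r - 1.0
    b = -(r * (p_a + p_f) - p_a - p_f + 1.0)
    c = r * p_a * p_f
    disc = b * b - 4 * a * c
    p11 = (-b - np.sqrt(disc)) / (2 * a)
    if not (max(0.0, p_a + p_f - 1.0) <= p11 <= min(p_a, p_f)):
        raise CohortConfigError("APOE4/FH odds ratio incompatible with marginals")
    return float(p11)


def _upper_quantile(p: float) -> float:
    """Threshold t with P(N(0,1) > t) = p; clipped to keep units finite."""
    return float(stats.norm.ppf(1.0 - np.clip(p, 1e-12, 1 - 1e-12)))


def _bin_ordinal(x: np.ndarray, probs) -> np.ndarray:
    cuts = stats.norm.ppf(np.cumsum(probs[:-1]))
    return np.searchsorted(cuts, x, side="right").astype(int)


def generate_cohort(
    config: GeneratorConfig, return_propensities: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a complete synthetic cohort (no missing values).

    With ``return_propensities=True`` also returns the table of latent
    standard-normal indicator propensities plus standardised age/sex, whose
    correlation matrix should match :func:`implied_propensity_corr`.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    lo, hi = cfg.age_range
    mu, sigma, ach_mean, ach_sd = _truncnorm_parent_params(cfg.age_mean, cfg.age_sd, lo, hi)
    a, b_ = (lo - mu) / sigma, (hi - mu) / sigma
    age = stats.truncnorm(a, b_, loc=mu, scale=sigma).rvs(size=n, random_state=rng)
    z_age = (age - ach_mean) / ach_sd  # standardise by achieved moments

    sex = (rng.random(n) < (1.0 - cfg.p_female)).astype(int)  # 1 = male
    p_male = 1.0 - cfg.p_female
    sd_sex = np.sqrt(p_male * (1 - p_male)) if 0 < p_male < 1 else 1.0
    z_sex = (sex - p_male) / sd_sex

    site = rng.choice(np.arange(1, len(cfg.site_weights) + 1), size=n, p=cfg.site_weights)

    fh = (rng.random(n) < cfg.p_family_history).astype(int)
    p11 = _fh_apoe4_joint(cfg.p_apoe4, cfg.p_family_history, cfg.fh_apoe4_odds_ratio)
    p_a_given_fh = p11 / cfg.p_family_history if cfg.p_family_history > 0 else 0.0
    p_a_given_nofh = (
        (cfg.p_apoe4 - p11) / (1 - cfg.p_family_history)
        if cfg.p_family_history < 1
        else 0.0
    )
    apoe4 = (rng.random(n) < np.where(fh == 1, p_a_given_fh, p_a_given_nofh)).astype(int)
    apoe4_c = apoe4 - cfg.p_apoe4

    # latent factors, unit variance
    risk = (
        cfg.risk_on_age * z_age
        + cfg.risk_on_sex * z_sex
        + np.sqrt(cfg._risk_resid_var()) * rng.standard_normal(n)
    )
    svd = (
        cfg.latent_path_risk_to_svd * risk
        + cfg.svd_on_age * z_age
        + cfg.interaction_apoe4 * apoe4_c * risk
        + np.sqrt(cfg._svd_resid_var()) * rng.standard_normal(n)
    )

    lam = cfg.all_loadings()
    latent_of = {k: risk for k in cfg.loadings_risk}
    latent_of.update({k: svd for k in cfg.loadings_svd})
    latent_of["epvs_cso"] = svd
    prop = {}
    for name in (*PROPENSITY_COLUMNS, "epvs_cso"):
        l = lam[name]
        prop[name] = l * latent_of[name] + np.sqrt(1 - l * l) * rng.standard_normal(n)

    df = pd.DataFrame(
        {
            "subject_id": [f"SUB{i:04d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "site": site,
            "apoe4": apoe4,
            "family_history": fh,
        }
    )
    df["education"] = cfg.education_mean + cfg.education_sd * prop["education"]
    df["sbp"] = 140.0 + cfg.sbp_sd * (prop["sbp"] - _upper_quantile(cfg.p_hypertension))
    # DBP tracks SBP; its own >= 90 criterion only triggers when SBP >= 140
    # already holds, so the hypertension marginal is governed by SBP alone.
    df["dbp"] = 0.55 * df["sbp"] + rng.normal(0.0, 2.5, size=n)
    whr_cut = np.where(sex == 1, 0.87, 0.78)
    df["whr"] = whr_cut + cfg.whr_sd * (prop["whr"] - _upper_quantile(cfg.p_obesity))
    df["alcohol"] = np.clip(
        21.0 + cfg.alcohol_sd * (prop["alcohol"] - _upper_quantile(cfg.p_high_alcohol)),
        0.0,
        None,
    )
    df["hearing_loss"] = (prop["hearing_loss"] > _upper_quantile(cfg.p_hearing_loss)).astype(int)
    df["tbi"] = (prop["tbi"] > _upper_quantile(cfg.p_tbi)).astype(int)

    wmh_cr = np.clip(cfg.wmh_cuberoot_mean + cfg.wmh_cuberoot_sd * prop["wmh"], 0.02, None)
    df["wmh_pct_tiv"] = wmh_cr**3
    df["wmh_cuberoot"] = wmh_cr

    df["epvs_bg"] = _bin_ordinal(prop["epvs_bg"], cfg.epvs_bg_probs)
    df["epvs_cso"] = _bin_ordinal(prop["epvs_cso"], cfg.epvs_cso_probs)
    faz_noise = 0.6 * rng.standard_normal(n)
    df["pv_fazekas"] = _bin_ordinal(0.8 * prop["wmh"] + faz_noise, cfg.pv_fazekas_probs)
    df["deep_fazekas"] = _bin_ordinal(
        0.8 * prop["wmh"] + 0.6 * rng.standard_normal(n), cfg.deep_fazekas_probs
    )

    cmb_any = (prop["cmb"] > _upper_quantile(cfg.p_cmb)).astype(int)
    lobar = (rng.random(n) < cfg.p_cmb_lobar_given_any).astype(int)
    deep = (rng.random(n) < cfg.p_cmb_deep_given_any).astype(int)
    lobar = np.where((lobar == 0) & (deep == 0), 1, lobar)  # at least one location
    df["cmb_lobar"] = cmb_any * lobar
    df["cmb_deep"] = cmb_any * deep
    df["cmb_any"] = cmb_any

    lac_any = (prop["lacunes"] > _upper_quantile(cfg.p_lacune)).astype(int)
    ldeep = (rng.random(n) < cfg.p_lacune_deep_given_any).astype(int)
    llobar = (rng.random(n) < cfg.p_lacune_lobar_given_any).astype(int)
    ldeep = np.where((ldeep == 0) & (llobar == 0), 1, ldeep)
    df["lacune_deep"] = lac_any * ldeep
    df["lacune_lobar"] = lac_any * llobar
    df["lacune_any"] = lac_any

    if return_propensities:
        pt = pd.DataFrame(prop)
        pt.insert(0, "z_sex", z_sex)
        pt.insert(0, "z_age", z_age)
        return df, pt
    return df


def implied_propensity_corr(config: GeneratorConfig) -> pd.DataFrame:
    """Model-implied correlation matrix of the indicator propensities.

    Built from the RAM (reticular action model) equations
    ``Sigma = (I - A)^-1 S (I - A)^-T`` over the variable ordering
    [z_age, z_sex, RISK, SVD, 10 indicator propensities], ignoring the
    APOE4-by-risk interaction term (whose contribution is folded into the
    SVD residual so every variance stays exactly 1).
    """
    config.validate()
    cfg = config
    names = ["z_age", "z_sex", "RISK", "SVD", *PROPENSITY_COLUMNS, "epvs_cso"]
    k = len(names)
    idx = {nm: i for i, nm in enumerate(names)}
    A = np.zeros((k, k))
    S = np.zeros((k, k))
    S[idx["z_age"], idx["z_age"]] = 1.0
    S[idx["z_sex"], idx["z_sex"]] = 1.0
    A[idx["RISK"], idx["z_age"]] = cfg.risk_on_age
    A[idx["RISK"], idx["z_sex"]] = cfg.risk_on_sex
    S[idx["RISK"], idx["RISK"]] = cfg._risk_resid_var()
    A[idx["SVD"], idx["RISK"]] = cfg.latent_path_risk_to_svd
    A[idx["SVD"], idx["z_age"]] = cfg.svd_on_age
    var_apoe = cfg.p_apoe4 * (1 - cfg.p_apoe4)
    S[idx["SVD"], idx["SVD"]] = (
        cfg._svd_resid_var() + cfg.interaction_apoe4**2 * var_apoe
    )
    lam = cfg.all_loadings()
    for name in (*PROPENSITY_COLUMNS, "epvs_cso"):
        latent = "RISK" if name in cfg.loadings_risk else "SVD"
        A[idx[name], idx[latent]] = lam[name]
        S[idx[name], idx[name]] = 1.0 - lam[name] ** 2
    binv = np.linalg.inv(np.eye(k) - A)
    sigma = binv @ S @ binv.T
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    keep = ["z_age", "z_sex", *PROPENSITY_COLUMNS, "epvs_cso"]
    out = pd.DataFrame(corr, index=names, columns=names)
    return out.loc[keep, keep]


def inject_missingness(
    cohort: pd.DataFrame, rates: Mapping[str, float], seed: int
) -> pd.DataFrame:
    """Delete entries completely at random, per-column, at the given rates."""
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise CohortConfigError(f"missingness rate for {col} outside [0, 1]: {rate}")
        if col not in cohort.columns:
            raise CohortConfigError(f"missingness rate given for unknown column {col!r}")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    for col in cohort.columns:  # stable column order for reproducibility
        rate = rates.get(col, 0.0)
        if rate > 0.0:
            mask = rng.random(len(out)) < rate
            out[col] = out[col].mask(mask)
    return out
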