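"""Non-SEM statistics: correlations, adjusted GLMs, FDR, rater agreement.

Covers the sensitivity and descriptive analyses that accompany the latent
variable models: Spearman correlations for unadjusted associations, linear
and logistic regressions adjusting for sex, mean-centred age and study
site, APOE4-stratified sensitivity fits, Benjamini-Hochberg false-discovery
control, and Cohen's kappa for inter-rater agreement on the visual SVD
ratings.  Regression fitting is delegated to statsmodels; this module owns
the covariate conventions (site dummy-coded against site 1, predictors
mean-centred) and the result shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "RegressionResult",
    "spearman",
    "fit_glm",
    "interaction_glm",
    "stratified_fit",
    "bh_fdr",
    "cohens_kappa",
]


@dataclass
class RegressionResult:
    """Coefficients and inference for one fitted linear/logistic model."""

    family: str
    coefficients: pd.Series
    standard_errors: pd.Series
    t_or_z_values: pd.Series
    p_values: pd.Series
    n_used: int
    perfect_fit: bool = False

    def row(self, term: str) -> dict[str, float]:
        return {
            "estimate": float(self.coefficients[term]),
            "se": float(self.standard_errors[term]),
            "stat": float(self.t_or_z_values[term]),
            "pvalue": float(self.p_values[term]),
        }


def spearman(x, y, method: str = "auto") -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    ``method="t"`` uses the t approximation for the p-value (adequate for
    cohort-sized samples); ``"exact"`` enumerates all rank permutations
    (only for n <= 8); ``"auto"`` picks exact for n <= 8.  Pairs with any
    missing value are dropped; at least 3 complete pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p_t = stats.spearmanr(x, y)
    if method == "t" or (method == "auto" and n > 8):
        return float(rho), float(p_t)
    if method not in ("exact", "auto"):
        raise ValueError(f"unknown method {method!r}")
    if n > 8:
        raise ValueError("exact permutation p-value limited to n <= 8")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(ry):
        r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return float(rho), count / total


def _design(
    df: pd.DataFrame,
    predictors: list[str],
    covariates: tuple[str, ...],
    center: bool,
) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for p in predictors:
        X[p] = df[p] - (df[p].mean() if center else 0.0)
    for c in covariates:
        if c == "site":
            dummies = pd.get_dummies(df["site"].astype(int), prefix="site", dtype=float)
            ref = sorted(int(s) for s in df["site"].dropna().unique())[0]
            dummies = dummies.drop(columns=f"site_{ref}")
            X = X.join(dummies)
        elif c == "age":
            X["age"] = df["age"] - (df["age"].mean() if center else 0.0)
        else:
            X[c] = df[c] - (df[c].mean() if center else 0.0)
    return sm.add_constant(X, has_constant="add")


def fit_glm(
    df: pd.DataFrame,
    outcome: str,
    predictors: list[str] | str,
    covariates: tuple[str, ...] = ("sex", "age", "site"),
    family: str = "linear",
    center: bool = True,
) -> RegressionResult:
    """Adjusted regression of one outcome on predictors plus covariates.

    Covariates default to sex (0 = female, 1 = male), age centred at the
    sample mean, and study site dummy-coded with the first site as
    reference.  All predictors are mean-centred (collinearity hygiene for
    product terms downstream).  Rows with missing values in any used column
    are dropped listwise.
    """
    if isinstance(predictors, str):
        predictors = [predictors]
    cols = [outcome] + predictors + [c for c in covariates]
    data = df[list(dict.fromkeys(cols))].dropna()
    n = len(data)
    X = _design(data, predictors, covariates, center)
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix rank deficient ({rank} < {X.shape[1]}); "
            "a predictor is constant or collinear"
        )
    y = data[outcome].astype(float)
    if family == "linear":
        res = sm.OLS(y, X.astype(float)).fit()
        perfect = bool(res.ssr <= 1e-12 * max(1.0, float(np.sum(y**2))))
    elif family == "logistic":
        if not set(y.dropna().unique()) <= {0.0, 1.0}:
            raise ValueError("logistic outcome must be 0/1")
        try:
            res = sm.GLM(y, X.astype(float), family=sm.families.Binomial()).fit()
        except PerfectSeparationError as err:
            raise ValueError(f"perfect separation detected in {outcome!r}") from err
        mu = res.fittedvalues
        perfect = bool(np.all((mu < 1e-8) | (mu > 1 - 1e-8)))
        if perfect:
            raise ValueError(f"perfect separation detected in {outcome!r}")
    else:
        raise ValueError(f"unknown family {family!r}")
    return RegressionResult(
        family=family,
        coefficients=res.params,
        standard_errors=res.bse,
        t_or_z_values=res.tvalues,
        p_values=res.pvalues,
        n_used=n,
        perfect_fit=perfect,
    )


def interaction_glm(
    df: pd.DataFrame,
    outcome: str,
    score: str,
    moderator: str,
    covariates: tuple[str, ...] = ("sex", "age", "site"),
    family: str = "linear",
) -> RegressionResult:
    """GLM with a mean-centred ``score x moderator`` product term.

    The interaction coefficient is reported under ``"<score>:<moderator>"``.
    """
    cols = list(dict.fromkeys([outcome, score, moderator, *covariates]))
    data = df[cols].dropna().copy()
    if data[moderator].nunique() < 2:
        raise ValueError(f"moderator {moderator!r} constant: model rank deficient")
    term = f"{score}:{moderator}"
    data[term] = (data[score] - data[score].mean()) * (
        data[moderator] - data[moderator].mean()
    )
    return fit_glm(
        data,
        outcome,
        [score, moderator, term],
        covariates=covariates,
        family=family,
    )


def stratified_fit(
    df: pd.DataFrame,
    stratum_var: str,
    outcome: str,
    predictors: list[str] | str,
    covariates: tuple[str, ...] = ("sex", "age", "site"),
    family: str = "linear",
) -> dict:
    """Independent fits of the same model within each stratum."""
    out = {}
    for level, sub in df.groupby(stratum_var):
        if len(sub) == 0:
            raise ValueError(f"empty stratum {level!r}")
        preds = [predictors] if isinstance(predictors, str) else predictors
        n_params = 1 + len(preds) + len(covariates)  # lower bound (site adds more)
        if len(sub.dropna(subset=[outcome])) <= n_params:
            raise ValueError(
                f"stratum {level!r} has too few observations for the model"
            )
        out[level] = fit_glm(sub, outcome, predictors, covariates, family)
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_kappa(table) -> float:
    """Cohen's kappa from a square k x k cross-tabulation of two raters."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("agreement table must be square")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("agreement table must hold non-negative counts")
    n = t.sum()
    if n <= 0:
        raise ValueError("agreement table is empty")
    po = np.trace(t) / n
    pe = float((t.sum(axis=0) / n) @ (t.sum(axis=1) / n))
    if abs(1.0 - pe) < 1e-12:
        raise ValueError("expected agreement is 1 (both raters constant): kappa undefined")
    return float((po - pe) / (1.0 - pe))
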