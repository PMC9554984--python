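"""Draw data from a specified SEM (for recovery and power studies).

Given a :class:`~svdrisk.semlib.model.ModelSpec` and a full assignment of
its free parameters, data are drawn from the multivariate normal with the
model-implied covariance (and mean vector, when the spec carries a mean
structure).  This simulates the model topology exactly, with no ordinal or
binary coarsening.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import ModelSpec

__all__ = ["simulate_from_spec", "two_factor_structural_model"]

# standardised loadings of the reference risk/SVD topology
_RISK_LOADINGS = {
    "sbp": 0.65,
    "whr": 0.60,
    "education": -0.45,
    "alcohol": 0.35,
    "hearing_loss": 0.35,
    "tbi": 0.30,
}
_SVD_LOADINGS = {
    "wmh_cuberoot": 0.70,
    "epvs_bg": 0.55,
    "cmb_any": 0.45,
    "lacune_any": 0.45,
}


def two_factor_structural_model(
    path: float = 0.80,
    risk_on_age: float = 0.25,
    risk_on_sex: float = 0.10,
    svd_on_age: float = 0.20,
    risk_loadings: dict[str, float] | None = None,
    svd_loadings: dict[str, float] | None = None,
):
    """The latent risk -> SVD structural topology on the standardised scale.

    Six indicators measure latent RISK, four measure latent SVD;
    SVD ~ RISK + age and RISK ~ age + sex, all variables unit variance in
    the generating model.  Because the fitted model anchors each latent to
    its first indicator (loading fixed to 1), the standardised inputs are
    converted to that raw parameterisation.  Returns ``(spec, values,
    truth)`` where ``values`` assigns every free parameter and ``truth``
    holds the generating raw and standardised Risk->SVD path for recovery
    checks.
    """
    lr = dict(_RISK_LOADINGS if risk_loadings is None else risk_loadings)
    ls = dict(_SVD_LOADINGS if svd_loadings is None else svd_loadings)
    risk_ind = list(lr)
    svd_ind = list(ls)
    text = (
        "RISK =~ " + " + ".join(risk_ind) + "\n"
        "SVD  =~ " + " + ".join(svd_ind) + "\n"
        "SVD  ~ RISK + age\n"
        "RISK ~ age + sex\n"
    )
    spec = ModelSpec.from_text(text)
    l1r = lr[risk_ind[0]]
    l1s = ls[svd_ind[0]]
    # latent* = lambda_1 * latent, so raw loadings divide by lambda_1 and
    # structural coefficients/variances rescale accordingly
    psi_risk = 1.0 - risk_on_age**2 - risk_on_sex**2
    psi_svd = 1.0 - (path**2 + svd_on_age**2 + 2 * path * svd_on_age * risk_on_age)
    if psi_risk <= 0 or psi_svd <= 0:
        raise ValueError("structural coefficients imply non-positive residual variance")
    values: dict[str, float] = {}
    for ind, lam in lr.items():
        if ind != risk_ind[0]:
            values[f"RISK=~{ind}"] = lam / l1r
        values[f"{ind}~~{ind}"] = 1.0 - lam * lam
    for ind, lam in ls.items():
        if ind != svd_ind[0]:
            values[f"SVD=~{ind}"] = lam / l1s
        values[f"{ind}~~{ind}"] = 1.0 - lam * lam
    raw_path = path * l1s / l1r
    values["SVD~RISK"] = raw_path
    values["SVD~age"] = svd_on_age * l1s
    values["RISK~age"] = risk_on_age * l1r
    values["RISK~sex"] = risk_on_sex * l1r
    values["RISK~~RISK"] = psi_risk * l1r * l1r
    values["SVD~~SVD"] = psi_svd * l1s * l1s
    values["age~~age"] = 1.0
    values["sex~~sex"] = 1.0
    values["age~~sex"] = 0.0
    truth = {"raw_path": raw_path, "std_path": path}
    return spec, values, truth


def simulate_from_spec(
    spec: ModelSpec,
    values: dict[str, float],
    n: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Sample ``n`` observations of the observed variables.

    ``values`` maps free-parameter labels (e.g. ``"SVD~RISK"``,
    ``"RISK~~RISK"``) to generating values; unspecified free parameters
    keep their start values, so pass every parameter you care about.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    theta = spec.theta_from_dict(values)
    sigma, mu = spec.implied_moments(theta)
    L = np.linalg.cholesky(sigma)  # raises if the implied covariance is not PD
    Z = rng.standard_normal((n, spec.n_obs))
    X = Z @ L.T
    if mu is not None:
        X = X + mu
    return pd.DataFrame(X, columns=spec.observed_vars)
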