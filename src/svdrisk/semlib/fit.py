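"""Maximum-likelihood SEM estimation.

Covariance-based ML minimises the discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

with the model chi-square ``(n - 1) * F_ML`` at the optimum.  Full-
information ML (FIML) maximises the casewise Gaussian log-likelihood over
each case's observed subset of variables (missingness patterns are grouped
for speed), with the saturated model estimated by EM so that the likelihood-
ratio chi-square ``2 * (loglik_sat - loglik_model)`` and the incremental
fit indices are available under missingness.

Gradients are analytic throughout, via the RAM derivative identities
``dSigma = u v' + v u'`` with u, v columns of F(I-A)^-1 and of
(I-A)^-1 S (I-A)^-T F'; variance parameters are optimised on the log scale
(gradient tolerance 1e-8 requested from the optimiser, with random restarts
on non-convergence).  Standard errors come from the inverse observed
information; modification indices are univariate score (Lagrange
multiplier) statistics for freeing one fixed edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ModelSpec, Parameter, SemSpecError

__all__ = [
    "SemFit",
    "SemFitError",
    "fit_ml",
    "fit_fiml",
    "fit_indices",
    "srmr_from_matrices",
    "modification_indices",
    "standardize",
    "trim_paths",
    "em_mvn",
]

_GTOL = 1e-8
_MAX_RESTARTS = 10


class SemFitError(RuntimeError):
    """Estimation failure (non-convergence, degenerate input)."""


@dataclass
class SemFit:
    """A fitted SEM with estimates, fit indices and diagnostics."""

    spec: ModelSpec
    method: str  # 'ml' or 'fiml'
    theta: np.ndarray
    estimates: pd.DataFrame  # index=label: est, se, z, pvalue
    standardized: pd.Series  # label -> standardised estimate (incl. fixed)
    chi_square: float
    df: int
    baseline_chi_square: float
    baseline_df: int
    n_used: int
    loglik: float
    cfi: float
    rmsea: float
    srmr: float
    converged: bool
    n_restarts: int
    sample_cov: pd.DataFrame | None = None
    sample_mean: pd.Series | None = None
    data: pd.DataFrame | None = field(default=None, repr=False)

    def estimate(self, label: str) -> float:
        return float(self.estimates.loc[label, "est"])

    def pvalue(self, label: str) -> float:
        return float(self.estimates.loc[label, "pvalue"])

    def se(self, label: str) -> float:
        return float(self.estimates.loc[label, "se"])

    def summary(self) -> str:
        lines = [
            f"SEM fit ({self.method}), n = {self.n_used}, converged = {self.converged}",
            f"chi2({self.df}) = {self.chi_square:.4f}, "
            f"CFI = {self.cfi:.4f}, RMSEA = {self.rmsea:.4f}, SRMR = {self.srmr:.4f}",
            "",
            self.estimates.join(self.standardized.rename("std")).to_string(
                float_format=lambda v: f"{v: .4f}"
            ),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_used": int(self.n_used),
            "converged": bool(self.converged),
            "chi_square": float(self.chi_square),
            "df": int(self.df),
            "cfi": float(self.cfi),
            "rmsea": float(self.rmsea),
            "srmr": float(self.srmr),
            "loglik": float(self.loglik),
            "estimates": {
                lab: {
                    "est": float(r["est"]),
                    "se": float(r["se"]),
                    "z": float(r["z"]),
                    "pvalue": float(r["pvalue"]),
                    "std": float(self.standardized.get(lab, np.nan)),
                }
                for lab, r in self.estimates.iterrows()
            },
        }


# --------------------------------------------------------------------- helpers


def _ram_workspaces(spec: ModelSpec, theta: np.ndarray):
    A, S, m = spec.matrices(theta)
    t, p = spec.n_total, spec.n_obs
    B = np.linalg.inv(np.eye(t) - A)
    C = B[:p, :]  # F B
    BSBt = B @ S @ B.T
    D = BSBt[:, :p]  # B S B' F'   (t x p, row j gives D[j, :])
    sigma = BSBt[:p, :p]
    Bm = B @ m
    mu = Bm[:p]
    return A, S, m, B, C, D, sigma, mu, Bm


def _dsigma_dot(spec: ModelSpec, C, D, Bm, E: np.ndarray, umean: np.ndarray | None):
    """Gradient contributions sum(E o dSigma_k) [+ umean . dmu_k] per free param."""
    grads = np.zeros(spec.n_free)
    EC = E @ C  # p x t
    ED = E @ D.T  # p x t  (columns j give E @ D[j, :])
    k = 0
    for prm in spec.parameters:
        if not prm.free:
            continue
        i, j = prm.row, prm.col
        if prm.matrix == "A":
            g = 2.0 * C[:, i] @ ED[:, j]
            if umean is not None:
                g += (umean @ C[:, i]) * Bm[j]
        elif prm.matrix == "S":
            if i == j:
                g = C[:, i] @ EC[:, i]
            else:
                g = 2.0 * C[:, i] @ EC[:, j]
        else:  # mean
            g = (umean @ C[:, i]) if umean is not None else 0.0
        grads[k] = g
        k += 1
    return grads


def _phi_pack(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    phi = theta.copy()
    for k, prm in enumerate(spec.free_parameters):
        if prm.is_variance:
            phi[k] = np.log(max(theta[k], 1e-10))
    return phi


def _phi_unpack(spec: ModelSpec, phi: np.ndarray) -> np.ndarray:
    theta = phi.copy()
    for k, prm in enumerate(spec.free_parameters):
        if prm.is_variance:
            theta[k] = np.exp(np.clip(phi[k], -40.0, 40.0))
    return theta


def _chain_to_phi(spec: ModelSpec, theta: np.ndarray, grad_theta: np.ndarray) -> np.ndarray:
    g = grad_theta.copy()
    for k, prm in enumerate(spec.free_parameters):
        if prm.is_variance:
            g[k] *= theta[k]
    return g


def _minimize(spec: ModelSpec, objective, theta0: np.ndarray, seed: int = 0):
    """L-BFGS on the log-variance scale with random restarts."""
    rng = np.random.default_rng(seed)
    best = None
    n_restarts = 0
    start = theta0.copy()
    for attempt in range(_MAX_RESTARTS + 1):
        phi0 = _phi_pack(spec, start)
        res = optimize.minimize(
            lambda ph: objective(_phi_unpack(spec, ph), spec),
            phi0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-14, "gtol": _GTOL},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        ok = np.isfinite(res.fun) and gnorm < 1e-5
        if best is None or (np.isfinite(res.fun) and res.fun < best[0].fun - 1e-12):
            best = (res, gnorm)
        if ok and res.fun <= best[0].fun + 1e-10:
            best = (res, gnorm)
            break
        n_restarts += 1
        scale = 0.25 * (1.0 + attempt)
        start = theta0 + rng.normal(0.0, scale, size=theta0.size) * (
            0.2 + np.abs(theta0)
        )
        # keep variance starts positive
        for k, prm in enumerate(spec.free_parameters):
            if prm.is_variance:
                start[k] = abs(start[k]) + 1e-3
    res, gnorm = best
    theta = _phi_unpack(spec, res.x)
    converged = bool(np.isfinite(res.fun) and gnorm < 1e-5)
    return theta, float(res.fun), converged, n_restarts


def _wrap_objective_grad(grad_theta_fn):
    def objective(theta, spec):
        f, g = grad_theta_fn(theta)
        return f, _chain_to_phi(spec, theta, g)

    return objective


def _numeric_hessian(grad_fn, theta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    d = theta.size
    H = np.zeros((d, d))
    for k in range(d):
        h = 1e-5 * (1.0 + abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        H[:, k] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _estimates_table(spec: ModelSpec, theta, cov_theta) -> pd.DataFrame:
    labels = spec.theta_labels()
    se = np.full(theta.size, np.nan)
    if cov_theta is not None:
        diag = np.diag(cov_theta)
        se = np.sqrt(np.where(diag > 0, diag, np.nan))
    z = theta / se
    pv = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"est": theta, "se": se, "z": z, "pvalue": pv}, index=labels)


def srmr_from_matrices(sample_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    """Root-mean-square standardised covariance residual (lower triangle + diag)."""
    s = np.asarray(sample_cov, dtype=float)
    sig = np.asarray(implied_cov, dtype=float)
    d = np.sqrt(np.diag(s))
    resid = (s - sig) / np.outer(d, d)
    tri = resid[np.tril_indices_from(resid)]
    return float(np.sqrt(np.mean(tri**2)))


def fit_indices(
    chi2_m: float,
    df_m: int,
    chi2_b: float,
    df_b: int,
    n: int,
    residuals: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """CFI, RMSEA and SRMR from chi-squares and a standardised residual matrix.

    CFI = 1 - max(chi2_m - df_m, 0) / max(chi2_b - df_b, chi2_m - df_m, 0);
    RMSEA = sqrt(max(chi2_m - df_m, 0) / (df_m * (n - 1))).  ``residuals``
    is the standardised residual moment matrix (may be None -> SRMR NaN).
    """
    num = max(chi2_m - df_m, 0.0)
    if num < 1e-8:  # optimiser dust on an exactly fitting model
        num = 0.0
    den = max(chi2_b - df_b, num, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    if df_m == 0:
        if chi2_m > 1e-6:
            raise ValueError("RMSEA undefined: df = 0 with non-zero chi-square")
        rmsea = 0.0
    else:
        rmsea = float(np.sqrt(num / (df_m * (n - 1))))
    if residuals is None:
        srmr = float("nan")
    else:
        tri = residuals[np.tril_indices_from(residuals)]
        srmr = float(np.sqrt(np.mean(tri**2)))
    return float(cfi), rmsea, srmr


# ----------------------------------------------------------------- ML fitting


def _starts_from_moments(spec: ModelSpec, S: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Data-driven start values: marker-scaled loadings, moment variances."""
    theta = spec.start_theta()
    diag = np.diag(S).copy()
    diag[~np.isfinite(diag) | (diag <= 0)] = 1.0
    marker: dict[int, int] = {}  # latent index -> marker indicator row
    for prm in spec.parameters:
        if (
            prm.matrix == "A"
            and not prm.free
            and prm.value == 1.0
            and prm.col >= spec.n_obs
            and prm.row < spec.n_obs
            and prm.col not in marker
        ):
            marker[prm.col] = prm.row
    for k, prm in enumerate(spec.free_parameters):
        if prm.matrix == "S" and prm.row == prm.col:
            if prm.row < spec.n_obs:
                exo = spec.names[prm.row] in spec.exogenous_vars
                theta[k] = diag[prm.row] * (1.0 if exo else 0.5)
            else:
                theta[k] = 0.4 * diag[marker[prm.row]] if prm.row in marker else 1.0
        elif (
            prm.matrix == "A"
            and prm.row < spec.n_obs
            and prm.col >= spec.n_obs
            and prm.col in marker
        ):
            mv = diag[marker[prm.col]]
            cov = S[prm.row, marker[prm.col]]
            if np.isfinite(cov) and mv > 0:
                theta[k] = cov / mv
        elif prm.matrix == "M":
            theta[k] = mean[prm.row] if prm.row < spec.n_obs else 0.0
    return theta


def _ml_starts(spec: ModelSpec, S: np.ndarray) -> np.ndarray:
    return _starts_from_moments(spec, S, np.zeros(spec.n_obs))


def fit_ml(
    sample_cov,
    n: int,
    spec: ModelSpec,
    se: bool = True,
    seed: int = 0,
) -> SemFit:
    """Fit a covariance-structure model by normal-theory maximum likelihood."""
    if spec.meanstructure:
        raise SemSpecError("fit_ml is covariance-only; use fit_fiml for mean structure")
    if isinstance(sample_cov, pd.DataFrame):
        order = spec.observed_vars
        missing = set(order) - set(sample_cov.columns)
        if missing:
            raise SemFitError(f"sample covariance lacks variables {sorted(missing)}")
        S = sample_cov.loc[order, order].to_numpy(dtype=float)
    else:
        S = np.asarray(sample_cov, dtype=float)
    p = spec.n_obs
    if S.shape != (p, p):
        raise SemFitError(f"sample covariance must be {p}x{p}")
    if not np.allclose(S, S.T, atol=1e-10):
        raise SemFitError("sample covariance not symmetric")
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError as err:
        raise SemFitError("sample covariance not positive definite") from err
    if n <= p:
        raise SemFitError(f"n = {n} too small for {p} observed variables")

    sign_s, logdet_s = np.linalg.slogdet(S)

    def f_and_grad(theta):
        try:
            _, _, _, _, C, D, sigma, _, Bm = _ram_workspaces(spec, theta)
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros(spec.n_free)
        sig_inv = np.linalg.inv(sigma)
        fval = (
            2.0 * np.sum(np.log(np.diag(L)))
            + float(np.sum(sig_inv * S))
            - logdet_s
            - p
        )
        E = sig_inv - sig_inv @ S @ sig_inv
        grad = _dsigma_dot(spec, C, D, Bm, E, None)
        return fval, grad

    theta0 = _ml_starts(spec, S)
    theta, fmin, converged, n_restarts = _minimize(
        spec, _wrap_objective_grad(f_and_grad), theta0, seed=seed
    )
    if not converged:
        raise SemFitError(
            f"ML estimation did not converge after {n_restarts} restarts "
            f"(final F = {fmin:.6g})"
        )

    chi2 = max((n - 1) * fmin, 0.0)
    df = spec.df
    dcorr = np.sqrt(np.diag(S))
    R = S / np.outer(dcorr, dcorr)
    chi2_b = float(-(n - 1) * np.linalg.slogdet(R)[1])
    df_b = p * (p - 1) // 2

    sigma_hat, _ = spec.implied_moments(theta)
    resid = (S - sigma_hat) / np.outer(dcorr, dcorr)
    cfi, rmsea, srmr = fit_indices(chi2, df, chi2_b, df_b, n, resid)

    cov_theta = None
    if se and spec.n_free:
        H = _numeric_hessian(lambda t: f_and_grad(t)[1], theta)
        try:
            cov_theta = 2.0 / (n - 1) * np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            cov_theta = None

    loglik = -0.5 * (n - 1) * (
        np.linalg.slogdet(sigma_hat)[1]
        + float(np.sum(np.linalg.inv(sigma_hat) * S))
        + p * np.log(2.0 * np.pi)
    )
    est = _estimates_table(spec, theta, cov_theta)
    return SemFit(
        spec=spec,
        method="ml",
        theta=theta,
        estimates=est,
        standardized=standardize(spec, theta),
        chi_square=chi2,
        df=df,
        baseline_chi_square=chi2_b,
        baseline_df=df_b,
        n_used=n,
        loglik=float(loglik),
        cfi=cfi,
        rmsea=rmsea,
        srmr=srmr,
        converged=converged,
        n_restarts=n_restarts,
        sample_cov=pd.DataFrame(S, index=spec.observed_vars, columns=spec.observed_vars),
    )


# --------------------------------------------------------------- FIML fitting


def _patterns(X: np.ndarray):
    obs = ~np.isnan(X)
    keep = obs.any(axis=1)
    X = X[keep]
    obs = obs[keep]
    out = []
    seen: dict[bytes, int] = {}
    for row_obs, row in zip(obs, X):
        key = row_obs.tobytes()
        if key not in seen:
            seen[key] = len(out)
            out.append([np.flatnonzero(row_obs), []])
        out[seen[key]][1].append(row)
    packed = []
    for o, rows in out:
        Z = np.asarray(rows)[:, o]
        packed.append((o, len(rows), Z.sum(axis=0), Z.T @ Z))
    return packed, int(keep.sum())


def em_mvn(X: np.ndarray, max_iter: int = 1000, tol: float = 1e-10):
    """EM estimate of a saturated multivariate normal under arbitrary MCAR/MAR
    missingness.  Returns (mean, cov, loglik) with ML (divisor-n) covariance."""
    X = np.asarray(X, dtype=float)
    keep = ~np.isnan(X).all(axis=1)
    X = X[keep]
    n, p = X.shape
    if n == 0:
        raise SemFitError("no observations")
    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    var[var <= 0] = 1.0
    sigma = np.diag(var)
    patt, _ = _patterns(X)
    prev = -np.inf
    ll = prev
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        ll = 0.0
        for o, n_g, s_g, ss_g in patt:
            m_idx = np.setdiff1d(np.arange(p), o)
            So = sigma[np.ix_(o, o)]
            L = np.linalg.cholesky(So)
            Pinv = np.linalg.inv(So)
            mu_o = mu[o]
            M = ss_g - np.outer(s_g, mu_o) - np.outer(mu_o, s_g) + n_g * np.outer(mu_o, mu_o)
            ll += -0.5 * (
                n_g * (len(o) * np.log(2 * np.pi) + 2 * np.sum(np.log(np.diag(L))))
                + float(np.sum(Pinv * M))
            )
            if len(m_idx) == 0:
                T1[o] += s_g
                T2[np.ix_(o, o)] += ss_g
                continue
            Smo = sigma[np.ix_(m_idx, o)]
            W = Smo @ Pinv
            cond_cov = sigma[np.ix_(m_idx, m_idx)] - W @ Smo.T
            # E[x_m | x_o] summed over cases
            em_sum = n_g * mu[m_idx] + W @ (s_g - n_g * mu_o)
            T1[o] += s_g
            T1[m_idx] += em_sum
            T2[np.ix_(o, o)] += ss_g
            cross = W @ (ss_g - np.outer(s_g, mu_o)) + np.outer(mu[m_idx], s_g)
            T2[np.ix_(m_idx, o)] += cross
            T2[np.ix_(o, m_idx)] += cross.T
            Mq = ss_g - np.outer(s_g, mu_o) - np.outer(mu_o, s_g) + n_g * np.outer(mu_o, mu_o)
            Emm = (
                n_g * cond_cov
                + n_g * np.outer(mu[m_idx], mu[m_idx])
                + W @ Mq @ W.T
                + np.outer(W @ (s_g - n_g * mu_o), mu[m_idx])
                + np.outer(mu[m_idx], W @ (s_g - n_g * mu_o))
            )
            T2[np.ix_(m_idx, m_idx)] += Emm
        mu = T1 / n
        sigma = T2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        if abs(ll - prev) < tol * (1.0 + abs(ll)):
            break
        prev = ll
    return mu, sigma, float(ll)


def fit_fiml(
    data: pd.DataFrame,
    spec: ModelSpec,
    se: bool = True,
    seed: int = 0,
) -> SemFit:
    """Fit by full-information ML over each case's observed variables.

    ``spec`` must carry a mean structure (every observed variable gets a
    free mean/intercept); rows with all model variables missing contribute
    no information and are excluded from ``n_used``.
    """
    if not spec.meanstructure:
        raise SemSpecError("fit_fiml requires a spec with meanstructure=True")
    missing_cols = set(spec.observed_vars) - set(data.columns)
    if missing_cols:
        raise SemFitError(f"data lacks model variables {sorted(missing_cols)}")
    X = data[spec.observed_vars].to_numpy(dtype=float)
    p = spec.n_obs
    never = [v for v, c in zip(spec.observed_vars, (~np.isnan(X)).sum(axis=0)) if c == 0]
    if never:
        raise SemFitError(f"variables never observed: {never}")
    patt, n_used = _patterns(X)
    if n_used == 0:
        raise SemFitError("all rows are completely missing")

    def negll_and_grad(theta):
        try:
            _, _, _, _, C, D, sigma, mu, Bm = _ram_workspaces(spec, theta)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros(spec.n_free)
        Etot = np.zeros((p, p))
        utot = np.zeros(p)
        ll = 0.0
        for o, n_g, s_g, ss_g in patt:
            So = sigma[np.ix_(o, o)]
            try:
                L = np.linalg.cholesky(So)
            except np.linalg.LinAlgError:
                return 1e10, np.zeros(spec.n_free)
            Pinv = np.linalg.inv(So)
            mu_o = mu[o]
            M = ss_g - np.outer(s_g, mu_o) - np.outer(mu_o, s_g) + n_g * np.outer(mu_o, mu_o)
            ll += -0.5 * (
                n_g * (len(o) * np.log(2 * np.pi) + 2.0 * np.sum(np.log(np.diag(L))))
                + float(np.sum(Pinv * M))
            )
            Etot[np.ix_(o, o)] += 0.5 * (Pinv @ M @ Pinv - n_g * Pinv)
            utot[o] += Pinv @ (s_g - n_g * mu_o)
        grad_ll = _dsigma_dot(spec, C, D, Bm, Etot, utot)
        return -ll, -grad_ll

    inv_n = 1.0 / n_used  # optimise the per-case mean loglik (O(1) gradients)

    def scaled(theta):
        f, g = negll_and_grad(theta)
        return f * inv_n, g * inv_n

    theta0 = _fiml_starts(spec, X)
    theta, negll_bar, converged, n_restarts = _minimize(
        spec, _wrap_objective_grad(scaled), theta0, seed=seed
    )
    if not converged:
        raise SemFitError(
            f"FIML estimation did not converge after {n_restarts} restarts"
        )
    ll_m = -negll_bar * n_used

    mu_sat, sigma_sat, ll_sat = em_mvn(X)
    ll_b = _independence_loglik(X)
    n_moments = p * (p + 3) // 2
    df = n_moments - spec.n_free
    df_b = n_moments - 2 * p
    chi2 = max(2.0 * (ll_sat - ll_m), 0.0)
    chi2_b = max(2.0 * (ll_sat - ll_b), 0.0)

    sigma_hat, _ = spec.implied_moments(theta)
    dsat = np.sqrt(np.diag(sigma_sat))
    resid = (sigma_sat - sigma_hat) / np.outer(dsat, dsat)
    cfi, rmsea, srmr = fit_indices(chi2, df, chi2_b, df_b, n_used, resid)

    cov_theta = None
    if se and spec.n_free:
        H = _numeric_hessian(lambda t: negll_and_grad(t)[1], theta)
        try:
            cov_theta = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            cov_theta = None

    est = _estimates_table(spec, theta, cov_theta)
    return SemFit(
        spec=spec,
        method="fiml",
        theta=theta,
        estimates=est,
        standardized=standardize(spec, theta),
        chi_square=chi2,
        df=df,
        baseline_chi_square=chi2_b,
        baseline_df=df_b,
        n_used=n_used,
        loglik=float(ll_m),
        cfi=cfi,
        rmsea=rmsea,
        srmr=srmr,
        converged=converged,
        n_restarts=n_restarts,
        sample_cov=pd.DataFrame(
            sigma_sat, index=spec.observed_vars, columns=spec.observed_vars
        ),
        sample_mean=pd.Series(mu_sat, index=spec.observed_vars),
        data=data,
    )


def _fiml_starts(spec: ModelSpec, X: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-nan slices handled below
        mean = np.nanmean(X, axis=0)
        df = pd.DataFrame(X)
        S = df.cov(ddof=0).to_numpy()  # pairwise-complete moments
    mean[~np.isfinite(mean)] = 0.0
    S[~np.isfinite(S)] = 0.0
    return _starts_from_moments(spec, S, mean)


def _independence_loglik(X: np.ndarray) -> float:
    """Saturated-means, diagonal-covariance Gaussian log-likelihood."""
    ll = 0.0
    for j in range(X.shape[1]):
        x = X[:, j]
        x = x[~np.isnan(x)]
        nj = x.size
        v = float(np.var(x))
        if v <= 0:
            raise SemFitError(f"variable column {j} is constant; baseline undefined")
        ll += -0.5 * nj * (np.log(2 * np.pi) + np.log(v) + 1.0)
    return float(ll)


# ------------------------------------------------------- standardised solution


def standardize(spec: ModelSpec, theta: np.ndarray) -> pd.Series:
    """Standardised estimates for every directed and symmetric parameter.

    Directed edges are rescaled by sd(source)/sd(target) with model-implied
    standard deviations over observed *and* latent variables; covariances
    become correlations; variances become the proportion of total variance
    (residual variance over implied variance of that variable).
    """
    sigma_all = spec.implied_full_covariance(theta)
    sd = np.sqrt(np.clip(np.diag(sigma_all), 1e-12, None))
    it = iter(theta)
    out: dict[str, float] = {}
    for prm in spec.parameters:
        val = next(it) if prm.free else prm.value
        i, j = prm.row, prm.col
        if prm.matrix == "A":
            out[prm.label] = val * sd[j] / sd[i]
        elif prm.matrix == "S":
            if i == j:
                out[prm.label] = val / sigma_all[i, i]
            else:
                out[prm.label] = val / (sd[i] * sd[j])
        else:
            out[prm.label] = val / sd[i]
    return pd.Series(out)


# ------------------------------------------------------- modification indices


def _dsigma_dmu_list(spec: ModelSpec, theta: np.ndarray):
    """Materialised derivative matrices (dSigma_k, dmu_k) per free parameter."""
    _, _, _, _, C, D, _, _, Bm = _ram_workspaces(spec, theta)
    p = spec.n_obs
    out = []
    for prm in spec.free_parameters:
        i, j = prm.row, prm.col
        dmu = np.zeros(p)
        if prm.matrix == "A":
            u, v = C[:, i], D[j, :]
            dS = np.outer(u, v) + np.outer(v, u)
            dmu = C[:, i] * Bm[j]
        elif prm.matrix == "S":
            if i == j:
                dS = np.outer(C[:, i], C[:, i])
            else:
                dS = np.outer(C[:, i], C[:, j]) + np.outer(C[:, j], C[:, i])
        else:
            dS = np.zeros((p, p))
            dmu = C[:, i].copy()
        out.append((dS, dmu))
    return out


def _expected_information(
    spec: ModelSpec, theta: np.ndarray, patt, n: int | None = None
) -> np.ndarray:
    """Fisher information of the free parameters.

    For complete-data covariance ML pass ``patt=None`` and ``n``:
    I_jk = (n-1)/2 tr(W dSigma_j W dSigma_k).  Under FIML the per-pattern
    submatrices and mean derivatives contribute.
    """
    derivs = _dsigma_dmu_list(spec, theta)
    d = len(derivs)
    sigma, mu = spec.implied_moments(theta)
    info = np.zeros((d, d))
    if patt is None:
        W = np.linalg.inv(sigma)
        WD = [W @ dS for dS, _ in derivs]
        for j in range(d):
            for k in range(j, d):
                info[j, k] = info[k, j] = 0.5 * (n - 1) * np.sum(WD[j] * WD[k].T)
        return info
    for o, n_g, _, _ in patt:
        W = np.linalg.inv(sigma[np.ix_(o, o)])
        WD = [W @ dS[np.ix_(o, o)] for dS, _ in derivs]
        Wm = [W @ dmu[o] for _, dmu in derivs]
        for j in range(d):
            for k in range(j, d):
                val = n_g * (
                    0.5 * np.sum(WD[j] * WD[k].T) + derivs[j][1][o] @ Wm[k]
                )
                info[j, k] += val
                if k > j:
                    info[k, j] += val
    return info


def default_mi_candidates(spec: ModelSpec) -> list[str]:
    """Cross-loadings and residual covariances absent from the model."""
    existing = {(p.matrix, p.row, p.col) for p in spec.parameters}
    existing |= {("S", p.col, p.row) for p in spec.parameters if p.matrix == "S"}
    cands = []
    ix = spec._idx
    for lv in spec.latent_vars:
        for ov in spec.observed_vars:
            if ("A", ix[ov], ix[lv]) not in existing:
                cands.append(f"{lv}=~{ov}")
    for a_i, a in enumerate(spec.observed_vars):
        for b in spec.observed_vars[a_i + 1 :]:
            if ("S", ix[a], ix[b]) not in existing:
                cands.append(f"{a}~~{b}")
    return cands


def _extended_spec(spec: ModelSpec, label: str) -> ModelSpec:
    import copy

    new = copy.deepcopy(spec)
    ix = new._idx
    if "=~" in label:
        lv, ov = (s.strip() for s in label.split("=~"))
        prm = Parameter("A", ix[ov], ix[lv], True, 0.0, label)
    elif "~~" in label:
        a, b = (s.strip() for s in label.split("~~"))
        prm = Parameter("S", ix[a], ix[b], True, 0.0, label)
    elif "~" in label:
        out, pred = (s.strip() for s in label.split("~"))
        prm = Parameter("A", ix[out], ix[pred], True, 0.0, label)
    else:
        raise SemSpecError(f"cannot parse candidate {label!r}")
    if any(
        p.matrix == prm.matrix
        and {(p.row, p.col), (p.col, p.row) if p.matrix == "S" else (p.row, p.col)}
        & {(prm.row, prm.col), (prm.col, prm.row) if prm.matrix == "S" else (prm.row, prm.col)}
        for p in new.parameters
    ):
        raise SemSpecError(f"parameter {label!r} already in the model")
    new.parameters.append(prm)
    new.free_parameters = [p for p in new.parameters if p.free]
    new.n_free = len(new.free_parameters)
    new._check_identification()
    return new


def modification_indices(
    fit: SemFit, candidates: list[str] | None = None
) -> pd.Series:
    """Score-test (Lagrange multiplier) statistic for freeing each fixed edge.

    Asymptotically chi-square(1); values above 3.84 flag re-specifications
    worth considering.  Candidates that would make the model unidentified
    are skipped.
    """
    if not fit.converged:
        raise SemFitError("modification indices require a converged fit")
    if candidates is None:
        candidates = default_mi_candidates(fit.spec)
    out = {}
    for label in candidates:
        try:
            ext = _extended_spec(fit.spec, label)
        except SemSpecError:
            continue
        theta_ext = np.append(fit.theta, 0.0)
        if fit.method == "ml":
            S = fit.sample_cov.to_numpy()
            n = fit.n_used
            g = _ml_grad_closure(ext, S)(theta_ext)
            U = -(n - 1) / 2.0 * g
            info = _expected_information(ext, theta_ext, None, n)
        else:
            X = fit.data[ext.observed_vars].to_numpy(dtype=float)
            patt, _ = _patterns(X)
            g = _fiml_grad_closure(ext, fit.data)(theta_ext)
            U = -g
            info = _expected_information(ext, theta_ext, patt)
        # univariate score statistic via the Schur complement of the
        # candidate's information given the estimated parameters
        a = info[-1, -1]
        b = info[:-1, -1]
        try:
            schur = a - b @ np.linalg.solve(info[:-1, :-1], b)
        except np.linalg.LinAlgError:
            continue
        if schur <= 1e-10:
            continue
        out[label] = float(U[-1] ** 2 / schur)
    return pd.Series(out, dtype=float).sort_values(ascending=False)


def _ml_grad_closure(spec: ModelSpec, S: np.ndarray):
    def grad(theta):
        _, _, _, _, C, D, sigma, _, Bm = _ram_workspaces(spec, theta)
        sig_inv = np.linalg.inv(sigma)
        E = sig_inv - sig_inv @ S @ sig_inv
        return _dsigma_dot(spec, C, D, Bm, E, None)

    return grad


def _fiml_grad_closure(spec: ModelSpec, data: pd.DataFrame):
    X = data[spec.observed_vars].to_numpy(dtype=float)
    patt, _ = _patterns(X)
    p = spec.n_obs

    def grad(theta):
        _, _, _, _, C, D, sigma, mu, Bm = _ram_workspaces(spec, theta)
        Etot = np.zeros((p, p))
        utot = np.zeros(p)
        for o, n_g, s_g, ss_g in patt:
            Pinv = np.linalg.inv(sigma[np.ix_(o, o)])
            mu_o = mu[o]
            M = ss_g - np.outer(s_g, mu_o) - np.outer(mu_o, s_g) + n_g * np.outer(mu_o, mu_o)
            Etot[np.ix_(o, o)] += 0.5 * (Pinv @ M @ Pinv - n_g * Pinv)
            utot[o] += Pinv @ (s_g - n_g * mu_o)
        return -_dsigma_dot(spec, C, D, Bm, Etot, utot)

    return grad


# ------------------------------------------------------------- path trimming


def trim_paths(
    fit_fn,
    spec: ModelSpec,
    trimmable: list[str],
    alpha: float = 0.05,
):
    """Sequentially drop the least significant trimmable path (Wald p >= alpha).

    ``fit_fn(spec) -> SemFit``.  One path is removed per step, the model is
    refitted, and the procedure stops when every remaining trimmable path is
    significant.  Returns (final_fit, final_spec, log) where log records the
    removal order with p-values.
    """
    log = []
    current = spec
    remaining = [t for t in trimmable]
    while True:
        fit = fit_fn(current)
        present = [t for t in remaining if t in fit.estimates.index]
        if not present:
            return fit, current, log
        pvals = {t: fit.pvalue(t) for t in present}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha:
            return fit, current, log
        log.append({"dropped": worst, "pvalue": pvals[worst]})
        current = current.drop_parameter(worst)
        remaining.remove(worst)
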