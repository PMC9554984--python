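"""Independent brute-force SEM fitter used only as a test oracle.

Shares no code with ``svdrisk.semlib``: the implied covariance is built by
reduced-form propagation (each variable expressed as a linear combination
of per-variable shocks via a topological pass, no matrix inversion of
I - A), the ML discrepancy is minimised by scipy L-BFGS-B with
finite-difference gradients and box bounds on variances, and the fit
indices are computed from their textbook definitions inline.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


class OracleModel:
    """A small acyclic SEM described by explicit edge lists.

    loadings: (latent, indicator, fixed or None);
    regressions: (outcome, predictor) free;
    covariances: (a, b) free shock covariances (off-diagonal).
    Every variable gets a free shock variance.
    """

    def __init__(self, observed, latents, loadings, regressions=(), covariances=()):
        self.observed = list(observed)
        self.latents = list(latents)
        self.all_vars = self.observed + self.latents
        self.loadings = list(loadings)
        self.regressions = list(regressions)
        self.covariances = list(covariances)

        self.free_labels = []
        for lv, ind, fixed in self.loadings:
            if fixed is None:
                self.free_labels.append(f"{lv}=~{ind}")
        for out, pred in self.regressions:
            self.free_labels.append(f"{out}~{pred}")
        for a, b in self.covariances:
            self.free_labels.append(f"{a}~~{b}")
        self.var_labels = [f"{v}~~{v}" for v in self.all_vars]
        self.free_labels += self.var_labels
        self.n_free = len(self.free_labels)

    # ---- reduced form: express every variable in the basis of shocks
    def implied_cov(self, values: dict[str, float]) -> np.ndarray:
        parents: dict[str, list[tuple[str, float]]] = {v: [] for v in self.all_vars}
        for lv, ind, fixed in self.loadings:
            coef = fixed if fixed is not None else values[f"{lv}=~{ind}"]
            parents[ind].append((lv, coef))
        for out, pred in self.regressions:
            parents[out].append((pred, values[f"{out}~{pred}"]))

        shock_of = {v: i for i, v in enumerate(self.all_vars)}
        k = len(self.all_vars)
        psi = np.zeros((k, k))
        for v in self.all_vars:
            psi[shock_of[v], shock_of[v]] = values[f"{v}~~{v}"]
        for a, b in self.covariances:
            psi[shock_of[a], shock_of[b]] = psi[shock_of[b], shock_of[a]] = values[
                f"{a}~~{b}"
            ]

        coefs: dict[str, np.ndarray] = {}

        def resolve(v, seen=()):
            if v in coefs:
                return coefs[v]
            if v in seen:
                raise ValueError("cyclic model")
            c = np.zeros(k)
            c[shock_of[v]] = 1.0
            for parent, w in parents[v]:
                c = c + w * resolve(parent, seen + (v,))
            coefs[v] = c
            return c

        for v in self.all_vars:
            resolve(v)
        C = np.vstack([coefs[v] for v in self.observed])
        return C @ psi @ C.T

    def fml(self, values: dict[str, float], S: np.ndarray) -> float:
        sigma = self.implied_cov(values)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e10
        p = S.shape[0]
        return float(
            logdet
            + np.trace(np.linalg.solve(sigma, S))
            - np.linalg.slogdet(S)[1]
            - p
        )

    def fit(self, S: np.ndarray, n: int):
        """Minimise F_ML; returns dict with estimates, chi2 and fit indices."""
        p = S.shape[0]
        start, lower = [], []
        diag = np.diag(S)
        for lab in self.free_labels:
            if "=~" in lab:
                start.append(0.5)
                lower.append(-np.inf)
            elif lab in self.var_labels:
                v = lab.split("~~")[0]
                start.append(0.5 * diag[self.observed.index(v)] if v in self.observed else 0.5)
                lower.append(1e-6)
            else:
                start.append(0.0)
                lower.append(-np.inf)

        def obj(x):
            return self.fml(dict(zip(self.free_labels, x)), S)

        best = None
        for attempt, x0 in enumerate(
            [np.array(start), np.array(start) * 1.5 + 0.05, np.array(start) * 0.5 + 0.2]
        ):
            res = optimize.minimize(
                obj,
                x0,
                method="L-BFGS-B",
                bounds=[(lo, None) for lo in lower],
                options={"maxiter": 10000, "ftol": 1e-15, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        values = dict(zip(self.free_labels, best.x))
        fmin = best.fun
        chi2 = (n - 1) * fmin
        # baseline: diagonal covariance, optimum at diag(S)
        f_base = float(
            np.sum(np.log(diag)) + p - np.linalg.slogdet(S)[1] - p
        )
        chi2_b = (n - 1) * f_base
        df = p * (p + 1) // 2 - self.n_free
        df_b = p * (p - 1) // 2
        num = max(chi2 - df, 0.0)
        den = max(chi2_b - df_b, chi2 - df, 0.0)
        cfi = 1.0 if den == 0 else 1.0 - num / den
        rmsea = 0.0 if df == 0 else np.sqrt(num / (df * (n - 1)))
        sigma = self.implied_cov(values)
        d = np.sqrt(diag)
        resid = (S - sigma) / np.outer(d, d)
        srmr = np.sqrt(np.mean(resid[np.tril_indices(p)] ** 2))
        return {
            "estimates": values,
            "chi2": float(chi2),
            "df": df,
            "cfi": float(cfi),
            "rmsea": float(rmsea),
            "srmr": float(srmr),
            "fmin": float(fmin),
        }


def random_small_model(rng: np.random.Generator):
    """A random 1- or 2-factor model plus simulated data, for oracle checks.

    Returns (oracle_model, spec_text, data) where the text parameterises the
    same model for the package fitter (marker loading fixed to 1 in both).
    """
    two = rng.random() < 0.5
    n1 = int(rng.integers(3, 5))
    n2 = int(rng.integers(3, 5)) if two else 0
    xs = [f"x{i}" for i in range(n1)]
    ys = [f"y{i}" for i in range(n2)]
    lam_x = 0.5 + 0.4 * rng.random(n1)
    lam_y = 0.5 + 0.4 * rng.random(n2) if two else np.array([])
    beta = float(0.3 + 0.4 * rng.random()) if two else 0.0
    n = 400
    f1 = rng.standard_normal(n)
    data = {}
    for name, lam in zip(xs, lam_x):
        data[name] = lam * f1 + np.sqrt(1 - lam**2) * rng.standard_normal(n)
    if two:
        f2 = beta * f1 + np.sqrt(1 - beta**2) * rng.standard_normal(n)
        for name, lam in zip(ys, lam_y):
            data[name] = lam * f2 + np.sqrt(1 - lam**2) * rng.standard_normal(n)

    loadings = [("F1", v, 1.0 if i == 0 else None) for i, v in enumerate(xs)]
    regressions = []
    if two:
        loadings += [("F2", v, 1.0 if i == 0 else None) for i, v in enumerate(ys)]
        regressions = [("F2", "F1")]
    oracle = OracleModel(xs + ys, ["F1", "F2"] if two else ["F1"], loadings, regressions)

    text = "F1 =~ " + " + ".join(xs) + "\n"
    if two:
        text += "F2 =~ " + " + ".join(ys) + "\nF2 ~ F1\n"
    import pandas as pd

    return oracle, text, pd.DataFrame(data)
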