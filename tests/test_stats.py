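"""Correlation, regression, FDR and agreement statistics vs closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svdrisk.statsuite import (
    bh_fdr,
    cohens_kappa,
    fit_glm,
    interaction_glm,
    spearman,
    stratified_fit,
)

from _oracles import oracle_bh, oracle_kappa, oracle_spearman_rho


def _glm_frame(rng, n=500, slope=0.5, logistic=False):
    df = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n),
            "age": rng.normal(51.2, 5.5, n),
            "site": rng.integers(1, 6, n),
            "x": rng.normal(0, 1, n),
        }
    )
    eta = slope * df["x"] + 0.02 * (df["age"] - df["age"].mean())
    if logistic:
        p = 1 / (1 + np.exp(-eta))
        df["y"] = (rng.random(n) < p).astype(int)
    else:
        df["y"] = eta + rng.normal(0, 1, n)
    return df


def test_spearman_monotone_extremes():
    x = np.arange(10.0)
    assert spearman(x, x**3)[0] == pytest.approx(1.0)
    assert spearman(x, -x - 2)[0] == pytest.approx(-1.0)


def test_spearman_ties_match_midrank_oracle(rng):
    x = rng.integers(0, 4, 60).astype(float)
    y = (x + rng.integers(0, 3, 60)).astype(float)
    rho, _ = spearman(x, y)
    assert rho == pytest.approx(oracle_spearman_rho(x, y), abs=1e-12)


def test_spearman_input_contracts():
    with pytest.raises(ValueError, match="complete pairs"):
        spearman([1, 2], [3, 4])
    with pytest.raises(ValueError, match="constant"):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])
    # missing pairs dropped before the n check
    rho, _ = spearman([1, 2, 3, np.nan], [2, 4, 6, 1])
    assert rho == pytest.approx(1.0)


def test_spearman_exact_permutation_small_n():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    y = [1.0, 3.0, 2.0, 5.0, 4.0, 6.0]
    rho, p_exact = spearman(x, y, method="exact")
    # p = share of permutations with |rho| >= observed; brute force is the
    # definition itself, so just sanity-bound it against the t approximation
    _, p_t = spearman(x, y, method="t")
    assert 0 < p_exact < 1
    assert abs(p_exact - p_t) < 0.15


def test_linear_glm_recovers_slope(rng):
    df = _glm_frame(rng, n=4000, slope=0.5)
    res = fit_glm(df, "y", "x")
    assert res.family == "linear"
    assert res.coefficients["x"] == pytest.approx(0.5, abs=0.05)
    assert res.n_used == 4000


def test_linear_glm_matches_numpy_lstsq(rng):
    """Same design, same listwise rows: coefficients equal lstsq to 1e-8."""
    df = _glm_frame(rng, n=200)
    res = fit_glm(df, "y", "x", covariates=("sex", "age"))
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["x"] - df["x"].mean(),
            df["sex"] - df["sex"].mean(),
            df["age"] - df["age"].mean(),
        ]
    )
    beta = np.linalg.lstsq(X, df["y"], rcond=None)[0]
    assert res.coefficients["x"] == pytest.approx(beta[1], abs=1e-8)
    # residual orthogonality to every design column (least-squares identity)
    resid = df["y"] - X @ beta
    assert np.abs(X.T @ resid).max() < 1e-8


def test_logistic_glm_recovers_log_odds(rng):
    df = _glm_frame(rng, n=4000, slope=np.log(2), logistic=True)
    res = fit_glm(df, "y", "x", family="logistic")
    assert res.coefficients["x"] == pytest.approx(np.log(2), abs=0.12)


def test_glm_degenerate_inputs():
    rng = np.random.default_rng(0)
    df = _glm_frame(rng, n=100)
    out = fit_glm(df.assign(y=df["age"]), "y", "age", covariates=("sex",))
    assert out.perfect_fit  # outcome identical to a predictor
    with pytest.raises(ValueError, match="rank deficient"):
        fit_glm(df.assign(x=1.0), "y", "x")
    sep = df.assign(y=(df["x"] > 0).astype(int))
    with pytest.raises(ValueError, match="separation"):
        fit_glm(sep, "y", "x", covariates=(), family="logistic")


def test_interaction_glm_sign_recovery(rng):
    n = 1500
    df = _glm_frame(rng, n=n)
    mod = rng.integers(0, 2, n)
    df["m"] = mod
    df["y"] = df["y"] - 0.4 * (df["x"] - df["x"].mean()) * (mod - mod.mean())
    res = interaction_glm(df, "y", "x", "m")
    assert res.coefficients["x:m"] < 0
    assert res.p_values["x:m"] < 0.01


def test_interaction_glm_constant_moderator_errors(rng):
    df = _glm_frame(rng, n=100).assign(m=1)
    with pytest.raises(ValueError, match="constant"):
        interaction_glm(df, "y", "x", "m")


def test_stratified_matches_unstratified_single_stratum(rng):
    df = _glm_frame(rng, n=300).assign(g=1)
    strat = stratified_fit(df, "g", "y", "x")
    whole = fit_glm(df, "y", "x")
    assert strat[1].coefficients["x"] == pytest.approx(whole.coefficients["x"], abs=1e-10)


def test_stratified_recovers_per_stratum_slopes(rng):
    n = 1200
    g = rng.integers(0, 2, n)
    df = _glm_frame(rng, n=n).assign(g=g)
    df["y"] = np.where(g == 1, 1.0, 0.2) * df["x"] + rng.normal(0, 1, n)
    strat = stratified_fit(df, "g", "y", "x")
    assert strat[0].coefficients["x"] == pytest.approx(0.2, abs=0.15)
    assert strat[1].coefficients["x"] == pytest.approx(1.0, abs=0.15)
    with pytest.raises(ValueError, match="too few"):
        stratified_fit(df.head(8), "g", "y", "x")


def test_bh_examples_and_oracle():
    assert bh_fdr([0.03]).tolist() == [0.03]
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
def test_bh_matches_bruteforce_stepup_and_is_monotone(ps):
    adj = bh_fdr(ps)
    assert np.allclose(adj, oracle_bh(ps), atol=1e-12)
    assert (adj >= np.asarray(ps) - 1e-12).all()
    order = np.argsort(ps, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_kappa_formula_cases():
    assert cohens_kappa([[10, 0], [0, 10]]) == pytest.approx(1.0)
    # independent raters with matching marginals: p_o == p_e -> kappa 0
    assert cohens_kappa([[1, 1], [1, 1]]) == pytest.approx(0.0)
    t = [[20, 5], [10, 65]]
    assert cohens_kappa(t) == pytest.approx(oracle_kappa(t), abs=1e-12)
    with pytest.raises(ValueError):
        cohens_kappa([[5, 0], [0, 0]])  # both raters constant
    with pytest.raises(ValueError):
        cohens_kappa([[1, 2, 3], [4, 5, 6]])  # not square


def test_kappa_agrees_with_sklearn_on_label_vectors(rng):
    sklearn = pytest.importorskip("sklearn.metrics")
    a = rng.integers(0, 3, 200)
    b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 3, 200))
    table = pd.crosstab(pd.Series(a), pd.Series(b)).reindex(
        index=range(3), columns=range(3), fill_value=0
    )
    assert cohens_kappa(table.to_numpy()) == pytest.approx(
        sklearn.cohen_kappa_score(a, b), abs=1e-12
    )
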