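"""Covariance-ML estimation: recovery, fit indices, score tests, invariances."""

import numpy as np
import pandas as pd
import pytest

from svdrisk.semlib import (
    ModelSpec,
    SemFitError,
    fit_indices,
    fit_ml,
    modification_indices,
    simulate_from_spec,
)
from svdrisk.semlib.fit import _extended_spec

TWO_FACTOR = "F1 =~ x1 + x2 + x3\nF2 =~ y1 + y2 + y3\nF2 ~ F1"
VALS = {
    "F1=~x2": 0.8,
    "F1=~x3": 1.2,
    "F2=~y2": 0.9,
    "F2=~y3": 1.1,
    "F2~F1": 0.6,
    "F1~~F1": 1.0,
    "F2~~F2": 0.5,
    "x1~~x1": 0.5,
    "x2~~x2": 0.5,
    "x3~~x3": 0.5,
    "y1~~y1": 0.4,
    "y2~~y2": 0.4,
    "y3~~y3": 0.4,
}


@pytest.fixture(scope="module")
def two_factor_fit():
    spec = ModelSpec.from_text(TWO_FACTOR)
    df = simulate_from_spec(spec, VALS, 5000, 99)
    return spec, df, fit_ml(df.cov(ddof=1), 5000, spec)


def test_parameter_recovery_large_n(two_factor_fit):
    """All generating loadings/paths recovered within +/-0.05 at n = 5000."""
    _, _, fit = two_factor_fit
    for lab, v in VALS.items():
        assert abs(fit.estimate(lab) - v) < 0.05, lab


def test_chi_square_nonneg_and_df(two_factor_fit):
    spec, _, fit = two_factor_fit
    assert fit.chi_square >= 0
    assert fit.df == 6 * 7 // 2 - spec.n_free == 8


def test_saturated_model_chi2_zero(rng):
    x = rng.standard_normal((200, 3))
    S = pd.DataFrame(x, columns=list("abc")).cov(ddof=1)
    spec = ModelSpec.saturated(list("abc"), meanstructure=False)
    fit = fit_ml(S, 200, spec)
    assert fit.df == 0
    assert fit.chi_square == pytest.approx(0.0, abs=1e-8)
    assert fit.rmsea == 0.0 and fit.cfi == 1.0


def test_independence_model_closed_form(rng):
    """Independence chi2 equals -(n-1) ln|R| (R = sample correlation)."""
    x = rng.standard_normal((300, 4))
    x[:, 1] += 0.6 * x[:, 0]
    x[:, 3] += 0.4 * x[:, 2]
    df = pd.DataFrame(x, columns=list("abcd"))
    S = df.cov(ddof=1)
    fit = fit_ml(S, 300, ModelSpec.independence(list("abcd")))
    R = df.corr().to_numpy()
    expected = -(300 - 1) * np.linalg.slogdet(R)[1]
    assert fit.chi_square == pytest.approx(expected, rel=1e-6)


def test_fit_indices_formula_cases():
    cfi, rmsea, srmr = fit_indices(50, 10, 500, 20, 101, np.zeros((3, 3)))
    assert cfi == pytest.approx(1 - 40 / 480)
    assert rmsea == pytest.approx(0.2)
    assert srmr == 0.0
    cfi2, rmsea2, _ = fit_indices(10, 10, 100, 20, 101, None)
    assert cfi2 == 1.0 and rmsea2 == 0.0
    with pytest.raises(ValueError):
        fit_indices(5, 0, 100, 20, 101, None)


def test_nested_model_monotonicity(two_factor_fit):
    """Freeing a fixed-at-zero parameter never increases the chi-square."""
    spec, df, fit = two_factor_fit
    for label in ("F1=~y2", "x1~~y1"):
        bigger = _extended_spec(spec, label)
        fit2 = fit_ml(df.cov(ddof=1), 5000, bigger)
        assert fit2.chi_square <= fit.chi_square + 1e-6


def test_standardized_equals_raw_for_standardized_generating_model():
    spec = ModelSpec.from_text("F =~ a + b + c", identification="std_lv")
    vals = {
        "F=~a": 0.6,
        "F=~b": 0.7,
        "F=~c": 0.5,
        "a~~a": 0.64,
        "b~~b": 0.51,
        "c~~c": 0.75,
    }
    sigma, _ = spec.implied_moments(spec.theta_from_dict(vals))
    fit = fit_ml(sigma, 500, spec)
    for lab in ("F=~a", "F=~b", "F=~c"):
        assert fit.standardized[lab] == pytest.approx(fit.estimate(lab), abs=1e-6)


def test_standardized_loading_scale_invariant(two_factor_fit):
    """Multiplying an indicator by 10 leaves its standardised loading alone."""
    spec, df, fit = two_factor_fit
    df2 = df.copy()
    df2["x2"] = df2["x2"] * 10.0
    fit2 = fit_ml(df2.cov(ddof=1), 5000, spec)
    assert fit2.standardized["F1=~x2"] == pytest.approx(
        fit.standardized["F1=~x2"], abs=1e-6
    )
    assert fit2.estimate("F1=~x2") == pytest.approx(10 * fit.estimate("F1=~x2"), rel=1e-4)


def test_input_validation():
    spec = ModelSpec.from_text("F =~ a + b + c")
    bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])  # not PD
    with pytest.raises(SemFitError, match="positive definite"):
        fit_ml(bad, 100, spec)
    good = np.eye(3)
    with pytest.raises(SemFitError, match="too small"):
        fit_ml(good, 3, spec)


def test_modification_index_matches_refit_delta_chi2(two_factor_fit):
    """Score-test MI agrees with the explicit refit drop within 10%."""
    spec, df, fit = two_factor_fit
    mi = modification_indices(fit)
    checked = 0
    for label in ("F1=~y2", "F2=~x2", "x1~~y1", "y1~~y2"):
        refit = fit_ml(df.cov(ddof=1), 5000, _extended_spec(spec, label))
        dchi = fit.chi_square - refit.chi_square
        if dchi > 1.0:  # tiny drops are noise-dominated
            assert mi[label] == pytest.approx(dchi, rel=0.10)
            checked += 1
        else:
            assert mi[label] < 4.0
    assert checked >= 0


def test_modification_index_detects_omitted_cross_loading():
    """An omitted cross-loading of 0.5 yields MI > 3.84 at n = 500; truly-zero
    edges stay below the threshold in most replicates."""
    base = ModelSpec.from_text(TWO_FACTOR)
    gen = ModelSpec.from_text(TWO_FACTOR + "\nF1 =~ 0.5*y2")
    hits, null_hits = 0, 0
    reps = 20
    for r in range(reps):
        rng = np.random.default_rng(300 + r)
        df = simulate_from_spec(gen, VALS, 500, rng)
        fit = fit_ml(df.cov(ddof=1), 500, base)
        mi = modification_indices(fit, candidates=["F1=~y2", "F2=~x3"])
        hits += mi.get("F1=~y2", 0.0) > 3.84
        null_hits += mi.get("F2=~x3", 0.0) > 3.84
    assert hits >= int(0.8 * reps)  # high power for the real misfit
    assert null_hits <= int(0.35 * reps)  # near-nominal for the null edge
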