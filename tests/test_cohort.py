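"""Synthetic cohort generator: determinism, calibration, latent structure."""

import numpy as np
import pandas as pd
import pytest

from svdrisk.cohort import (
    CohortConfigError,
    GeneratorConfig,
    generate_cohort,
    implied_propensity_corr,
    inject_missingness,
)


def test_seed_determinism_byte_identical():
    a = generate_cohort(GeneratorConfig(n_subjects=200, seed=3))
    b = generate_cohort(GeneratorConfig(n_subjects=200, seed=3))
    assert a.to_csv(index=False) == b.to_csv(index=False)
    c = generate_cohort(GeneratorConfig(n_subjects=200, seed=4))
    assert a.to_csv(index=False) != c.to_csv(index=False)


def test_invariants_hold(default_cohort):
    df = default_cohort
    assert df["age"].between(40, 59).all()
    assert (df["sbp"] > df["dbp"]).all()
    assert (df["whr"] > 0).all()
    assert (df["alcohol"] >= 0).all()
    assert df["site"].isin([1, 2, 3, 4, 5]).all()
    assert df["epvs_bg"].between(0, 4).all()
    assert df["pv_fazekas"].between(0, 3).all()
    assert (df["wmh_pct_tiv"] >= 0).all()
    # location flags only where a lesion is present
    assert (df.loc[df.cmb_any == 0, ["cmb_deep", "cmb_lobar"]] == 0).all().all()
    assert (df.loc[df.cmb_any == 1, ["cmb_deep", "cmb_lobar"]].max(axis=1) == 1).all()


def test_female_proportion_near_target(default_cohort):
    """Sample female share within +/-4% of the 61.6% target at n = 630."""
    assert abs((1 - default_cohort["sex"].mean()) - 0.616) < 0.04


def test_marginal_calibration_large_n(big_cohort):
    """Every binary marginal within +/-2% of its configured target (n = 6000)."""
    df, cfg = big_cohort, GeneratorConfig()
    checks = {
        "female": (1 - df.sex.mean(), 0.616),
        "apoe4": (df.apoe4.mean(), cfg.p_apoe4),
        "fh": (df.family_history.mean(), cfg.p_family_history),
        "hypertension": (((df.sbp >= 140) | (df.dbp >= 90)).mean(), cfg.p_hypertension),
        "obesity": (
            (df.whr >= np.where(df.sex == 1, 0.87, 0.78)).mean(),
            cfg.p_obesity,
        ),
        "alcohol": ((df.alcohol > 21).mean(), cfg.p_high_alcohol),
        "hearing": (df.hearing_loss.mean(), cfg.p_hearing_loss),
        "tbi": (df.tbi.mean(), cfg.p_tbi),
        "cmb": (df.cmb_any.mean(), cfg.p_cmb),
        "lacune": (df.lacune_any.mean(), cfg.p_lacune),
    }
    for name, (got, want) in checks.items():
        assert abs(got - want) < 0.02, (name, got, want)
    assert abs(df.age.mean() - 51.2) < 0.2
    assert abs(df.wmh_pct_tiv.mean() - 0.13) < 0.02


def test_fh_apoe4_enrichment(big_cohort):
    """APOE4 enrichment among FH-positive subjects near the configured OR of 2."""
    t = pd.crosstab(big_cohort.family_history, big_cohort.apoe4)
    odds_ratio = (t.loc[1, 1] * t.loc[0, 0]) / (t.loc[1, 0] * t.loc[0, 1])
    assert 1.5 < odds_ratio < 2.7


def test_zero_loadings_give_independent_indicators():
    cfg = GeneratorConfig(
        n_subjects=4000,
        seed=5,
        loadings_risk={k: 0.0 for k in GeneratorConfig().loadings_risk},
        loadings_svd={k: 0.0 for k in GeneratorConfig().loadings_svd},
        loading_epvs_cso=0.0,
    )
    _, prop = generate_cohort(cfg, return_propensities=True)
    corr = prop.drop(columns=["z_age", "z_sex"]).corr().to_numpy()
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    assert np.abs(off).max() < 0.06  # sampling error only


def test_sample_correlations_match_ram_implied():
    """Propensity correlations match the RAM-implied covariance elementwise
    within +/-0.03 at path 0.8.  The check is a maximum over ~80 correlation
    entries whose individual sampling error is ~n^-1/2, so n = 20000 keeps
    the noise floor safely below the stated elementwise tolerance."""
    # interaction off: the implied covariance describes the linear part only
    cfg = GeneratorConfig(
        n_subjects=20000, seed=21, latent_path_risk_to_svd=0.8, interaction_apoe4=0.0
    )
    _, prop = generate_cohort(cfg, return_propensities=True)
    emp = prop.corr().to_numpy()
    imp = implied_propensity_corr(cfg).to_numpy()
    assert np.abs(emp - imp).max() < 0.03


def test_invalid_configs_rejected():
    with pytest.raises(CohortConfigError):
        GeneratorConfig(p_apoe4=1.4).validate()
    with pytest.raises(CohortConfigError):
        GeneratorConfig(loadings_svd={"wmh": 1.2, "epvs_bg": 0.5, "cmb": 0.4, "lacunes": 0.4}).validate()
    with pytest.raises(CohortConfigError):
        GeneratorConfig(n_subjects=0).validate()
    with pytest.raises(CohortConfigError, match="positive-definite"):
        GeneratorConfig(latent_path_risk_to_svd=0.95, svd_on_age=0.5).validate()


def test_missingness_rates():
    df = generate_cohort(GeneratorConfig(n_subjects=1000, seed=9))
    same = inject_missingness(df, {"education": 0.0}, seed=1)
    pd.testing.assert_frame_equal(df, same)
    m = inject_missingness(df, {"wmh_pct_tiv": 0.05}, seed=1)
    k = m["wmh_pct_tiv"].isna().sum()
    assert 30 <= k <= 70  # binomial(1000, .05) 99.99% interval
    allgone = inject_missingness(df, {"education": 1.0}, seed=1)
    assert allgone["education"].isna().all()
    with pytest.raises(CohortConfigError):
        inject_missingness(df, {"education": 1.5}, seed=1)
    with pytest.raises(CohortConfigError):
        inject_missingness(df, {"not_a_column": 0.1}, seed=1)


def test_missingness_reproducible():
    df = generate_cohort(GeneratorConfig(n_subjects=500, seed=2))
    a = inject_missingness(df, {"sbp": 0.2}, seed=8)
    b = inject_missingness(df, {"sbp": 0.2}, seed=8)
    assert a["sbp"].isna().equals(b["sbp"].isna())


def test_config_yaml_roundtrip(tmp_path):
    cfg = GeneratorConfig(n_subjects=123, seed=42, latent_path_risk_to_svd=0.5)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = GeneratorConfig.from_yaml(path)
    assert back == cfg
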