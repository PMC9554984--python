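"""End-to-end analysis pipeline: cohort -> scores -> SEM -> sensitivity.

Stages, in order:

1. load or synthesise the cohort (with per-column missingness);
2. sample-characteristics table (Table-1 style);
3. composite SVD scores and modifiable-risk flags/score;
4. CFA of the two measurement models (latent RISK from the six risk
   indicators, latent SVD from the four imaging markers);
5. gate: the structural model is fitted only if both measurement models
   reach acceptable fit (CFI >= 0.95 passes outright; >= 0.90 proceeds with
   a warning; RMSEA and SRMR must be below 0.10), unless forced;
6. full structural model (SVD ~ RISK + age [+ sex + APOE4], RISK ~ age +
   sex [+ APOE4]) with optional sequential Wald trimming of the
   non-significant APOE4/sex paths, then BH-FDR over the structural paths;
7. APOE4-by-risk interaction SEM with the observed composite risk score;
8. sensitivity analyses: Spearman and covariate-adjusted GLMs per SVD
   marker for family history and APOE4, risk-score regressions on the
   composite SVD scores, the interaction GLM, and APOE4-stratified fits.

Continuous SEM indicators are z-scaled before fitting (standardised
coefficients are scale-free; raw-scale variances differing by four orders
of magnitude would only slow the optimiser).  Every stage is seeded from
the config and the run log echoes config and seed, so any number in the
bundle is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import risk as risk_mod
from . import scoring
from .cohort import GeneratorConfig, generate_cohort, inject_missingness
from .semlib import (
    ModelSpec,
    SemFit,
    fit_fiml,
    fit_interaction_model,
    fit_ml,
    trim_paths,
)
from .statsuite import bh_fdr, fit_glm, interaction_glm, spearman, stratified_fit

__all__ = [
    "AnalysisConfig",
    "PipelineError",
    "ReportBundle",
    "run_pipeline",
    "summarize_table1",
    "RISK_INDICATORS",
    "SVD_INDICATORS",
]

# sbp first: the marker indicator fixes the latent's scale and sign, so it
# must load positively on risk (education loads negatively)
RISK_INDICATORS = ("sbp", "whr", "education", "alcohol", "hearing_loss", "tbi")
SVD_INDICATORS = ("wmh_cuberoot", "epvs_bg", "cmb_any", "lacune_any")
_CONTINUOUS_INDICATORS = ("education", "sbp", "whr", "alcohol", "wmh_cuberoot")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Pipeline configuration: exactly one of ``input_csv`` / ``generator``."""

    input_csv: str | None = None
    generator: GeneratorConfig | None = None
    seed: int = 0
    trimming: bool = True
    force: bool = False
    apply_missingness: bool = True
    cfi_pass: float = 0.95
    cfi_warn: float = 0.90
    rmsea_max: float = 0.10
    srmr_max: float = 0.10
    fdr_scope: str = "structural"
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError("provide exactly one of input_csv or generator config")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        gen = d.pop("generator", None)
        if gen is not None:
            for key in (
                "age_range",
                "epvs_bg_probs",
                "epvs_cso_probs",
                "pv_fazekas_probs",
                "deep_fazekas_probs",
                "site_weights",
            ):
                if key in gen:
                    gen[key] = tuple(gen[key])
            gen = GeneratorConfig(**gen)
        return cls(generator=gen, **d)


@dataclass
class ReportBundle:
    table1: pd.DataFrame
    table2: pd.DataFrame
    risk_distribution: pd.Series
    cfa_risk: SemFit
    cfa_svd: SemFit
    gate: dict
    structural: SemFit | None
    structural_paths: pd.DataFrame | None
    trim_log: list
    interaction: SemFit | None
    sensitivity: dict
    cohort: pd.DataFrame
    log: list[str] = field(default_factory=list)

    def to_files(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(out / "cohort_scored.csv", index=False)
        self.table1.to_csv(out / "table1.csv")
        self.table2.to_csv(out / "table2.csv", index=False)
        self.risk_distribution.to_csv(out / "risk_factor_distribution.csv")
        sems = {"cfa_risk": self.cfa_risk.to_dict(), "cfa_svd": self.cfa_svd.to_dict()}
        if self.structural is not None:
            sems["structural"] = self.structural.to_dict()
        if self.interaction is not None:
            sems["interaction"] = self.interaction.to_dict()
        sems["gate"] = self.gate
        sems["trim_log"] = self.trim_log
        (out / "sem_summaries.json").write_text(json.dumps(sems, indent=2))
        if self.structural_paths is not None:
            self.structural_paths.to_csv(out / "structural_paths.csv", index=False)
        (out / "sensitivity.json").write_text(
            json.dumps(self.sensitivity, indent=2, default=float)
        )
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")


def summarize_table1(cohort: pd.DataFrame) -> pd.DataFrame:
    """Sample characteristics: mean (SD) or %, plus missing counts."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    continuous = ["age", "education", "wmh_pct_tiv", "epvs_bg"]
    binary = [
        ("sex", "% male"),
        ("apoe4", "% carriers"),
        ("family_history", "% positive"),
        ("hearing_loss", "% positive"),
        ("tbi", "% positive"),
        ("cmb_any", "% present"),
        ("lacune_any", "% present"),
    ]
    rows = []
    for col in continuous:
        if col not in cohort.columns:
            continue
        x = cohort[col]
        rows.append(
            {
                "variable": col,
                "statistic": "mean (SD)",
                "value": float(x.mean()),
                "sd": float(x.std()),
                "n_missing": int(x.isna().sum()),
            }
        )
    for col, label in binary:
        if col not in cohort.columns:
            continue
        x = cohort[col]
        rows.append(
            {
                "variable": col,
                "statistic": label,
                "value": float(100.0 * x.mean()),
                "sd": np.nan,
                "n_missing": int(x.isna().sum()),
            }
        )
    for col in ("global_svd", "caa", "hypertensive_arteriopathy", "risk_score"):
        if col in cohort.columns:
            x = pd.to_numeric(cohort[col], errors="coerce")
            rows.append(
                {
                    "variable": col,
                    "statistic": "mean (SD)",
                    "value": float(x.mean()),
                    "sd": float(x.std()),
                    "n_missing": int(x.isna().sum()),
                }
            )
    return pd.DataFrame(rows).set_index("variable")


def _prepare(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derived columns with missingness propagation."""
    df = cohort.copy()
    if "wmh_pct_tiv" in df.columns:
        df["wmh_cuberoot"] = df["wmh_pct_tiv"].astype(float) ** (1.0 / 3.0)
    df["cmb_any"] = df[["cmb_deep", "cmb_lobar"]].max(axis=1, skipna=False)
    df["lacune_any"] = df[["lacune_deep", "lacune_lobar"]].max(axis=1, skipna=False)
    return df


def _zscale(df: pd.DataFrame, cols) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        x = out[c].astype(float)
        sd = x.std()
        if not np.isfinite(sd) or sd == 0:
            raise PipelineError("sem", f"indicator {c!r} is constant")
        out[c] = (x - x.mean()) / sd
    return out


def _fit_measurement(df: pd.DataFrame, latent: str, indicators, seed: int) -> SemFit:
    text = f"{latent} =~ " + " + ".join(indicators)
    cols = list(indicators)
    sub = df[cols]
    if sub.notna().all(axis=None):
        spec = ModelSpec.from_text(text)
        return fit_ml(sub.cov(ddof=1), len(sub), spec, seed=seed)
    spec = ModelSpec.from_text(text, meanstructure=True)
    return fit_fiml(sub, spec, seed=seed)


def _gate(cfg: AnalysisConfig, fits: dict[str, SemFit], log: list[str]) -> dict:
    gate = {"passed": True, "warnings": [], "detail": {}}
    for name, fit in fits.items():
        ok = (
            fit.cfi >= cfg.cfi_warn
            and fit.rmsea <= cfg.rmsea_max
            and fit.srmr <= cfg.srmr_max
        )
        level = "pass" if fit.cfi >= cfg.cfi_pass and ok else ("warn" if ok else "fail")
        gate["detail"][name] = {
            "cfi": fit.cfi,
            "rmsea": fit.rmsea,
            "srmr": fit.srmr,
            "level": level,
        }
        if level == "warn":
            gate["warnings"].append(f"{name}: CFI {fit.cfi:.3f} below {cfg.cfi_pass}")
        if level == "fail":
            gate["passed"] = False
        log.append(
            f"[gate] {name}: CFI={fit.cfi:.4f} RMSEA={fit.rmsea:.4f} "
            f"SRMR={fit.srmr:.4f} -> {level}"
        )
    return gate


_STRUCTURAL_TEXT = """
RISK =~ sbp + whr + education + alcohol + hearing_loss + tbi
SVD  =~ wmh_cuberoot + epvs_bg + cmb_any + lacune_any
SVD  ~ RISK + age + sex + apoe4
RISK ~ age + sex + apoe4
"""
_TRIMMABLE = ["SVD~apoe4", "RISK~apoe4", "SVD~sex"]


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    cfg = config
    log: list[str] = [f"seed = {cfg.seed}"]

    # ---- stage: cohort
    try:
        if cfg.generator is not None:
            gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
            cohort = generate_cohort(gen)
            if cfg.apply_missingness and gen.missingness:
                cohort = inject_missingness(cohort, gen.missingness, seed=cfg.seed + 1)
            log.append(f"generated cohort n={len(cohort)} (config echo: {gen})")
        else:
            cohort = pd.read_csv(cfg.input_csv)
            log.append(f"loaded cohort n={len(cohort)} from {cfg.input_csv}")
        if "exclude" in cohort.columns:
            n0 = len(cohort)
            cohort = cohort[cohort["exclude"].fillna(0).astype(int) == 0].copy()
            log.append(f"excluded {n0 - len(cohort)} flagged rows")
        cohort = _prepare(cohort)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("cohort", str(err)) from err

    # ---- stage: scores
    try:
        comp = scoring.score_cohort(cohort)
        cohort = pd.concat([cohort, comp], axis=1)
        cohort = risk_mod.add_risk_columns(cohort)
        risk_dist = risk_mod.risk_factor_distribution(cohort["n_risk_flags"])
        log.append(
            "risk-flag distribution (0/1/2/3+): "
            + "/".join(f"{v:.3f}" for v in risk_dist)
        )
    except Exception as err:
        raise PipelineError("scores", str(err)) from err

    try:
        table1 = summarize_table1(cohort)
    except Exception as err:
        raise PipelineError("table1", str(err)) from err

    # ---- stage: CFA
    try:
        zdf = _zscale(cohort, [c for c in _CONTINUOUS_INDICATORS])
        cfa_risk = _fit_measurement(zdf, "RISK", RISK_INDICATORS, cfg.seed)
        cfa_svd = _fit_measurement(zdf, "SVD", SVD_INDICATORS, cfg.seed)
    except Exception as err:
        raise PipelineError("cfa", str(err)) from err
    gate = _gate(cfg, {"risk": cfa_risk, "svd": cfa_svd}, log)

    structural = None
    structural_paths = None
    trim_log: list = []
    interaction = None
    if gate["passed"] or cfg.force:
        if not gate["passed"]:
            log.append("[gate] failed but --force given; fitting structural model")
        # ---- stage: structural SEM
        try:
            sem_df = zdf.copy()
            sem_df["age"] = (sem_df["age"] - sem_df["age"].mean()) / sem_df["age"].std()
            cols = list(RISK_INDICATORS + SVD_INDICATORS) + ["age", "sex", "apoe4"]
            complete = sem_df[cols].notna().all(axis=None)

            def fit_fn(spec_in):
                if complete:
                    return fit_ml(
                        sem_df[spec_in.observed_vars].cov(ddof=1),
                        len(sem_df),
                        spec_in,
                        seed=cfg.seed,
                    )
                return fit_fiml(sem_df[cols], spec_in, seed=cfg.seed)

            spec = ModelSpec.from_text(
                _STRUCTURAL_TEXT, meanstructure=not complete
            )
            if cfg.trimming:
                structural, spec, trim_log = trim_paths(fit_fn, spec, list(_TRIMMABLE))
                for step in trim_log:
                    log.append(
                        f"[trim] dropped {step['dropped']} (p = {step['pvalue']:.4f})"
                    )
            else:
                structural = fit_fn(spec)
            path_labels = [
                lab
                for lab in structural.estimates.index
                if lab.startswith(("SVD~", "RISK~")) and "~~" not in lab and lab[-2:] != "~1"
            ]
            structural_paths = structural.estimates.loc[path_labels].copy()
            structural_paths.insert(0, "path", path_labels)
            structural_paths["std_beta"] = [
                structural.standardized[lab] for lab in path_labels
            ]
            structural_paths["p_fdr"] = bh_fdr(structural_paths["pvalue"].to_numpy())
            log.append(
                "[structural] "
                + ", ".join(
                    f"{lab}: beta={structural.standardized[lab]:.3f} "
                    f"p={structural.pvalue(lab):.4f}"
                    for lab in path_labels
                )
            )
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError("structural", str(err)) from err

        # ---- stage: interaction SEM
        try:
            idf = zdf.copy()
            interaction = fit_interaction_model(idf, seed=cfg.seed)
            ilab = "SVD~risk_x_apoe4"
            log.append(
                f"[interaction] beta={interaction.standardized[ilab]:.3f} "
                f"p={interaction.pvalue(ilab):.4f}"
            )
        except Exception as err:
            raise PipelineError("interaction", str(err)) from err
    else:
        log.append("[gate] measurement fit inadequate; structural stages skipped")

    # ---- stage: sensitivity
    try:
        table2, sensitivity = _sensitivity(cohort, log)
    except Exception as err:
        raise PipelineError("sensitivity", str(err)) from err

    return ReportBundle(
        table1=table1,
        table2=table2,
        risk_distribution=risk_dist,
        cfa_risk=cfa_risk,
        cfa_svd=cfa_svd,
        gate=gate,
        structural=structural,
        structural_paths=structural_paths,
        trim_log=trim_log,
        interaction=interaction,
        sensitivity=sensitivity,
        cohort=cohort,
        log=log,
    )


_MARKERS = (
    ("wmh_cuberoot", "linear"),
    ("epvs_bg", "linear"),
    ("cmb_any", "logistic"),
    ("lacune_any", "logistic"),
)


def _sensitivity(cohort: pd.DataFrame, log: list[str]):
    rows = []
    for group in ("family_history", "apoe4"):
        for marker, family in _MARKERS:
            sub = cohort[[marker, group]].dropna()
            rho, p_rho = spearman(sub[marker], sub[group])
            res = fit_glm(cohort, marker, group, family=family)
            r = res.row(group)
            rows.append(
                {
                    "marker": marker,
                    "group": group,
                    "rho": rho,
                    "p_unadjusted": p_rho,
                    "stat_adjusted": r["stat"],
                    "p_adjusted": r["pvalue"],
                    "n_used": res.n_used,
                }
            )
    table2 = pd.DataFrame(rows)

    sens: dict = {}
    for score_col in ("global_svd", "caa", "hypertensive_arteriopathy"):
        dfc = cohort.copy()
        dfc[score_col] = pd.to_numeric(dfc[score_col], errors="coerce")
        res = fit_glm(dfc, score_col, "risk_score", family="linear")
        sens[f"risk_to_{score_col}"] = res.row("risk_score") | {"n_used": res.n_used}
    dfc = cohort.copy()
    dfc["hypertensive_arteriopathy"] = pd.to_numeric(
        dfc["hypertensive_arteriopathy"], errors="coerce"
    )
    ires = interaction_glm(dfc, "hypertensive_arteriopathy", "risk_score", "apoe4")
    sens["interaction_glm_ha"] = ires.row("risk_score:apoe4") | {"n_used": ires.n_used}
    log.append(
        f"[sensitivity] interaction GLM on HA: t={sens['interaction_glm_ha']['stat']:.3f} "
        f"p={sens['interaction_glm_ha']['pvalue']:.4f}"
    )
    strat = stratified_fit(dfc, "apoe4", "hypertensive_arteriopathy", "risk_score")
    sens["stratified_ha_by_apoe4"] = {
        str(level): r.row("risk_score") | {"n_used": r.n_used}
        for level, r in strat.items()
    }
    return table2, sens
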