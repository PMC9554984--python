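"""Modifiable midlife dementia risk factors: dichotomisation and scoring.

Six early/midlife modifiable risk factors from the 2020 Lancet Commission
on dementia prevention are dichotomised at published cut-offs:

* low education: < 13 years of education
* hearing loss: self-reported (already binary)
* traumatic brain injury (TBI): >= 1 head injury with loss of consciousness
  (already binary)
* high alcohol intake: > 21 units/week
* hypertension: systolic BP >= 140 mmHg or diastolic BP >= 90 mmHg (NICE
  NG136 clinic thresholds)
* obesity: waist-to-hip ratio >= 0.78 for females, >= 0.87 for males

The composite midlife risk score assigns 1 point per positive flag except
hypertension and obesity, which carry 2 points each (they load most
strongly on the latent risk construct), so the total ranges 0-8.  Missing
inputs propagate: a flag whose inputs are unavailable is missing (never
silently 0), and any missing flag makes the composite score missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FLAG_COLUMNS",
    "RISK_WEIGHTS",
    "dichotomize",
    "dichotomize_cohort",
    "composite_risk_score",
    "add_risk_columns",
    "risk_factor_distribution",
]

FLAG_COLUMNS = (
    "low_education",
    "hearing_loss",
    "tbi",
    "high_alcohol",
    "hypertension",
    "obesity",
)

RISK_WEIGHTS = {
    "low_education": 1,
    "hearing_loss": 1,
    "tbi": 1,
    "high_alcohol": 1,
    "hypertension": 2,
    "obesity": 2,
}

# WHR obesity cut-offs by sex (0 = female, 1 = male)
_WHR_CUT = {0: 0.78, 1: 0.87}


@dataclass(frozen=True)
class RiskScore:
    total: int
    n_flags_positive: int

    def __post_init__(self) -> None:
        if not 0 <= self.total <= 8:
            raise ValueError(f"total {self.total} outside 0-8")
        if not 0 <= self.n_flags_positive <= 6:
            raise ValueError(f"n_flags_positive {self.n_flags_positive} outside 0-6")


def _flag(cond) -> float:
    if cond is None or (isinstance(cond, float) and np.isnan(cond)):
        return np.nan
    return float(bool(cond))


def dichotomize(record) -> dict[str, float]:
    """Dichotomise one subject's measurements into the six risk flags.

    ``record`` is any mapping (dict, Series, dataclass-as-dict) with keys
    ``education`` (years), ``hearing_loss``, ``tbi`` (binary), ``alcohol``
    (units/week), ``sbp``/``dbp`` (mmHg), ``whr``, ``sex`` (0 = female,
    1 = male).  Missing inputs give NaN flags.
    """
    get = record.get if hasattr(record, "get") else lambda k, d=None: getattr(record, k, d)

    def val(name):
        v = get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    edu, alcohol = val("education"), val("alcohol")
    sbp, dbp = val("sbp"), val("dbp")
    whr, sex = val("whr"), val("sex")

    flags: dict[str, float] = {}
    flags["low_education"] = np.nan if edu is None else float(edu < 13)
    flags["hearing_loss"] = _flag(val("hearing_loss"))
    flags["tbi"] = _flag(val("tbi"))
    flags["high_alcohol"] = np.nan if alcohol is None else float(alcohol > 21)
    if sbp is None and dbp is None:
        flags["hypertension"] = np.nan
    elif sbp is not None and dbp is not None:
        flags["hypertension"] = float(sbp >= 140 or dbp >= 90)
    else:
        # one pressure observed: positive if it crosses its threshold,
        # otherwise unknowable -> missing
        known = sbp if sbp is not None else dbp
        cut = 140 if sbp is not None else 90
        flags["hypertension"] = 1.0 if known >= cut else np.nan
    if whr is None or sex is None or int(sex) not in _WHR_CUT:
        flags["obesity"] = np.nan
    else:
        flags["obesity"] = float(whr >= _WHR_CUT[int(sex)])
    return flags


def dichotomize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Row-wise :func:`dichotomize` over a cohort table."""
    rows = [dichotomize(row) for _, row in cohort.iterrows()]
    return pd.DataFrame(rows, index=cohort.index)[list(FLAG_COLUMNS)]


def composite_risk_score(flags) -> RiskScore | None:
    """Weighted composite score from the six flags; ``None`` if any missing."""
    get = flags.get if hasattr(flags, "get") else lambda k: getattr(flags, k)
    vals = {}
    for name in FLAG_COLUMNS:
        v = get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        if v not in (0, 1, 0.0, 1.0):
            raise ValueError(f"flag {name}={v!r} not binary")
        vals[name] = int(v)
    total = sum(RISK_WEIGHTS[k] * v for k, v in vals.items())
    return RiskScore(total=total, n_flags_positive=sum(vals.values()))


def add_risk_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append flag columns plus ``risk_score`` and ``n_risk_flags`` to a cohort."""
    flags = dichotomize_cohort(cohort)
    out = cohort.copy()
    for col in FLAG_COLUMNS:  # overwrite raw self-report columns of same name
        out[col] = flags[col]
    complete = flags.notna().all(axis=1)
    w = np.array([RISK_WEIGHTS[c] for c in FLAG_COLUMNS], dtype=float)
    totals = flags.to_numpy(dtype=float) @ w
    out["risk_score"] = np.where(complete, totals, np.nan)
    out["n_risk_flags"] = np.where(complete, flags.sum(axis=1), np.nan)
    return out


def risk_factor_distribution(n_flags: pd.Series) -> pd.Series:
    """Proportion of subjects with 0, 1, 2, and >= 3 positive risk flags.

    Missing counts are excluded; proportions sum to 1 over non-missing.
    """
    x = pd.Series(n_flags).dropna().astype(int)
    if (x < 0).any() or (x > 6).any():
        raise ValueError("flag counts outside 0-6")
    n = len(x)
    out = pd.Series(
        {
            "0": (x == 0).sum() / n if n else np.nan,
            "1": (x == 1).sum() / n if n else np.nan,
            "2": (x == 2).sum() / n if n else np.nan,
            "3+": (x >= 3).sum() / n if n else np.nan,
        },
        name="proportion",
    )
    return out
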