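"""Composite cerebral small-vessel-disease (SVD) scores from visual ratings.

Each participant carries semi-quantitative MRI ratings of the four SVD
markers: Fazekas white-matter-hyperintensity grades (periventricular and
deep, 0-3), enlarged-perivascular-space (EPVS) severity bins (basal ganglia
and centrum semiovale, 0-4), and presence/absence of cerebral microbleeds
(CMB) and lacunes, each split by deep vs lobar location.  Three composite
0-4 scores summarise them:

* ``global_svd`` -- total SVD burden (Staals-style rule: one point each for
  any lacune, any CMB, basal-ganglia EPVS >= 2, and confluent WMH).
* ``caa`` -- cerebral amyloid angiopathy subtype (lobar-predominant markers).
* ``hypertensive_arteriopathy`` -- deep-perforator subtype (deep markers).

The rules are represented as explicit criterion tables so that a variant
rule set (e.g. a different WMH criterion for the global score) can be
swapped in without touching the scoring machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SvdRatings",
    "CompositeScores",
    "RATING_COLUMNS",
    "epvs_score_from_count",
    "caa_score",
    "ha_score",
    "global_svd_score",
    "score_cohort",
    "GLOBAL_SVD_RULE",
    "CAA_RULE",
    "HA_RULE",
]

#: rating columns required to compute all three composite scores
RATING_COLUMNS = (
    "pv_fazekas",
    "deep_fazekas",
    "epvs_bg",
    "epvs_cso",
    "cmb_deep",
    "cmb_lobar",
    "lacune_deep",
    "lacune_lobar",
)

_ORDINAL_RANGES = {
    "pv_fazekas": 3,
    "deep_fazekas": 3,
    "epvs_bg": 4,
    "epvs_cso": 4,
}
_BINARY_FIELDS = ("cmb_deep", "cmb_lobar", "lacune_deep", "lacune_lobar")


@dataclass(frozen=True)
class SvdRatings:
    """One subject's visual SVD ratings.

    Fazekas grades are 0-3, EPVS bins 0-4; microbleed and lacune fields are
    presence flags (only definite lesions; 'possible' microbleeds are
    excluded upstream).  ``wmh_pct_tiv`` is the quantitative WMH volume as a
    percentage of total intracranial volume and is carried along but not
    used by the composite rules.
    """

    pv_fazekas: int
    deep_fazekas: int
    epvs_bg: int
    epvs_cso: int
    cmb_deep: int
    cmb_lobar: int
    lacune_deep: int
    lacune_lobar: int
    wmh_pct_tiv: float | None = None

    def __post_init__(self) -> None:
        for name, hi in _ORDINAL_RANGES.items():
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= hi):
                raise ValueError(f"{name}={v!r} outside ordinal range 0-{hi}")
        for name in _BINARY_FIELDS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name}={v!r} not a 0/1 presence flag")
        if self.wmh_pct_tiv is not None and self.wmh_pct_tiv < 0:
            raise ValueError("wmh_pct_tiv must be >= 0")


@dataclass(frozen=True)
class CompositeScores:
    global_svd: int
    caa: int
    hypertensive_arteriopathy: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v not in (0, 1, 2, 3, 4):
                raise ValueError(f"{f.name}={v!r} outside 0-4")


# A rule is an ordered tuple of (criterion name, predicate on SvdRatings).
Rule = Sequence[tuple[str, Callable[[SvdRatings], bool]]]

CAA_RULE: Rule = (
    ("lobar_lacune", lambda r: r.lacune_lobar >= 1),
    ("lobar_cmb", lambda r: r.cmb_lobar >= 1),
    ("epvs_cso_ge2", lambda r: r.epvs_cso >= 2),
    ("wmh_burden", lambda r: r.pv_fazekas == 3 or r.deep_fazekas >= 2),
)

HA_RULE: Rule = (
    ("deep_lacune", lambda r: r.lacune_deep >= 1),
    ("deep_cmb", lambda r: r.cmb_deep >= 1),
    ("epvs_bg_ge2", lambda r: r.epvs_bg >= 2),
    ("deep_wmh_ge2", lambda r: r.deep_fazekas >= 2),
)

GLOBAL_SVD_RULE: Rule = (
    ("any_lacune", lambda r: r.lacune_deep >= 1 or r.lacune_lobar >= 1),
    ("any_cmb", lambda r: r.cmb_deep >= 1 or r.cmb_lobar >= 1),
    ("epvs_bg_ge2", lambda r: r.epvs_bg >= 2),
    ("wmh_burden", lambda r: r.pv_fazekas == 3 or r.deep_fazekas >= 2),
)


def epvs_score_from_count(count: int) -> int:
    """Bin a per-region EPVS lesion count into the ordinal 0-4 severity score.

    0 = none, 1 = 1-10, 2 = 11-20, 3 = 21-40, 4 = more than 40 lesions.
    """
    if not isinstance(count, (int, np.integer)) or isinstance(count, bool):
        raise TypeError(f"EPVS count must be an integer, got {count!r}")
    if count < 0:
        raise ValueError(f"EPVS count must be non-negative, got {count}")
    if count == 0:
        return 0
    if count <= 10:
        return 1
    if count <= 20:
        return 2
    if count <= 40:
        return 3
    return 4


def _apply_rule(r: SvdRatings, rule: Rule) -> int:
    return sum(bool(pred(r)) for _, pred in rule)


def caa_score(r: SvdRatings, rule: Rule = CAA_RULE) -> int:
    """CAA subtype score: one point per lobar-predominant criterion met."""
    return _apply_rule(r, rule)


def ha_score(r: SvdRatings, rule: Rule = HA_RULE) -> int:
    """Hypertensive-arteriopathy subtype score: one point per deep criterion."""
    return _apply_rule(r, rule)


def global_svd_score(r: SvdRatings, rule: Rule = GLOBAL_SVD_RULE) -> int:
    """Total SVD burden score (one point per marker class present)."""
    return _apply_rule(r, rule)


def score_cohort(
    ratings: pd.DataFrame,
    rules: Mapping[str, Rule] | None = None,
) -> pd.DataFrame:
    """Compute the three composite scores for every row of a ratings table.

    Rows with any missing rating yield missing scores for all three
    composites (missingness propagates; no partial credit).  Output is
    row-aligned with the input index, columns ``global_svd``, ``caa``,
    ``hypertensive_arteriopathy`` (nullable integers).
    """
    missing_cols = [c for c in RATING_COLUMNS if c not in ratings.columns]
    if missing_cols:
        raise ValueError(f"ratings table lacks required columns: {missing_cols}")
    if rules is None:
        rules = {
            "global_svd": GLOBAL_SVD_RULE,
            "caa": CAA_RULE,
            "hypertensive_arteriopathy": HA_RULE,
        }
    out = pd.DataFrame(
        index=ratings.index,
        columns=list(rules.keys()),
        dtype="Int64",
    )
    sub = ratings[list(RATING_COLUMNS)]
    complete = sub.notna().all(axis=1)
    for idx in ratings.index[complete]:
        row = sub.loc[idx]
        r = SvdRatings(**{c: int(row[c]) for c in RATING_COLUMNS})
        for name, rule in rules.items():
            out.at[idx, name] = _apply_rule(r, rule)
    return out
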