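"""Composite SVD scores against the published criteria and a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from svdrisk.scoring import (
    RATING_COLUMNS,
    CompositeScores,
    SvdRatings,
    caa_score,
    epvs_score_from_count,
    global_svd_score,
    ha_score,
    score_cohort,
)

from _oracles import (
    all_rating_combinations,
    oracle_caa,
    oracle_epvs_bin,
    oracle_global,
    oracle_ha,
)


def _ratings(**kw) -> SvdRatings:
    base = dict(
        pv_fazekas=0,
        deep_fazekas=0,
        epvs_bg=0,
        epvs_cso=0,
        cmb_deep=0,
        cmb_lobar=0,
        lacune_deep=0,
        lacune_lobar=0,
    )
    base.update(kw)
    return SvdRatings(**base)


@pytest.mark.parametrize(
    "count,expected",
    [(0, 0), (1, 1), (10, 1), (11, 2), (15, 2), (20, 2), (21, 3), (40, 3), (41, 4), (400, 4)],
)
def test_epvs_count_bins(count, expected):
    """Severity bins: 0 none, 1-10, 11-20, 21-40, >40."""
    assert epvs_score_from_count(count) == expected


def test_epvs_rejects_invalid_counts():
    with pytest.raises(ValueError):
        epvs_score_from_count(-1)
    with pytest.raises(TypeError):
        epvs_score_from_count(2.5)


def test_epvs_matches_piecewise_oracle():
    for c in range(0, 120):
        assert epvs_score_from_count(c) == oracle_epvs_bin(c)


def test_caa_examples():
    assert caa_score(_ratings()) == 0
    assert caa_score(_ratings(cmb_lobar=1, epvs_cso=3)) == 2
    assert caa_score(_ratings(lacune_lobar=1, cmb_lobar=1, epvs_cso=2, pv_fazekas=3)) == 4


def test_ha_examples():
    assert ha_score(_ratings()) == 0
    assert ha_score(_ratings(lacune_deep=1)) == 1
    assert ha_score(_ratings(lacune_deep=1, cmb_deep=1, epvs_bg=2, deep_fazekas=2)) == 4


def test_global_examples():
    assert global_svd_score(_ratings()) == 0
    assert global_svd_score(_ratings(lacune_lobar=1)) == 1
    assert (
        global_svd_score(
            _ratings(
                pv_fazekas=3,
                deep_fazekas=3,
                epvs_bg=4,
                epvs_cso=4,
                cmb_deep=1,
                cmb_lobar=1,
                lacune_deep=1,
                lacune_lobar=1,
            )
        )
        == 4
    )


def test_exhaustive_equivalence_and_monotonicity():
    """All 6400 rating combinations match the independent oracle, scores stay
    in 0-4, and raising any single marker never lowers any score."""
    scores = {}
    for combo in all_rating_combinations():
        r = SvdRatings(*combo)
        got = (global_svd_score(r), caa_score(r), ha_score(r))
        exp = (oracle_global(*combo), oracle_caa(*combo), oracle_ha(*combo))
        assert got == exp, combo
        assert all(0 <= s <= 4 for s in got)
        scores[combo] = got
    maxes = (3, 3, 4, 4, 1, 1, 1, 1)
    for combo, sc in scores.items():
        for k in range(8):
            if combo[k] < maxes[k]:
                stepped = list(combo)
                stepped[k] += 1
                up = scores[tuple(stepped)]
                assert all(u >= s for u, s in zip(up, sc)), (combo, k)


def test_subtype_scores_are_logically_independent():
    """Pure lobar disease maxes CAA with HA 0 and vice versa."""
    lobar = _ratings(lacune_lobar=1, cmb_lobar=1, epvs_cso=2, pv_fazekas=3)
    assert caa_score(lobar) == 4 and ha_score(lobar) == 0
    deep = _ratings(lacune_deep=1, cmb_deep=1, epvs_bg=2, deep_fazekas=0, pv_fazekas=0)
    assert ha_score(deep) == 3 and caa_score(deep) == 0
    deep_full = _ratings(lacune_deep=1, cmb_deep=1, epvs_bg=2, deep_fazekas=2)
    assert ha_score(deep_full) == 4


def test_ratings_validation():
    with pytest.raises(ValueError):
        _ratings(pv_fazekas=4)
    with pytest.raises(ValueError):
        _ratings(epvs_bg=5)
    with pytest.raises(ValueError):
        _ratings(cmb_deep=2)
    with pytest.raises(ValueError):
        CompositeScores(5, 0, 0)


def test_score_cohort_missingness_and_alignment():
    df = pd.DataFrame(
        [
            dict(zip(RATING_COLUMNS, (3, 2, 2, 2, 1, 1, 1, 1))),
            dict(zip(RATING_COLUMNS, (0, 0, 0, 0, 0, 0, 0, 0))),
        ],
        index=["a", "b"],
    )
    df.loc["c"] = dict(zip(RATING_COLUMNS, (1, 1, 1, 1, np.nan, 0, 0, 0)))
    out = score_cohort(df)
    assert list(out.index) == ["a", "b", "c"]
    assert out.loc["a", "global_svd"] == 4
    assert out.loc["b"].tolist() == [0, 0, 0]
    assert out.loc["c"].isna().all()  # one missing CMB rating blanks all three


def test_score_cohort_empty_and_malformed():
    empty = pd.DataFrame(columns=list(RATING_COLUMNS))
    assert len(score_cohort(empty)) == 0
    with pytest.raises(ValueError, match="required columns"):
        score_cohort(pd.DataFrame({"pv_fazekas": [1]}))
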