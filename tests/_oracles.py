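"""Independently coded brute-force oracles for the test suite.

Everything here is deliberately written without reusing any svdrisk
implementation code: scores are recomputed from the published criteria with
plain arithmetic, BH by the literal step-up definition, Spearman as Pearson
on midranks, kappa from the contingency-table formula.
"""

from __future__ import annotations

import numpy as np


def oracle_caa(pv_faz, deep_faz, epvs_bg, epvs_cso, cmb_deep, cmb_lobar, lac_deep, lac_lobar):
    pts = 0
    if lac_lobar >= 1:
        pts += 1
    if cmb_lobar >= 1:
        pts += 1
    if epvs_cso >= 2:
        pts += 1
    if pv_faz == 3 or deep_faz >= 2:
        pts += 1
    return pts


def oracle_ha(pv_faz, deep_faz, epvs_bg, epvs_cso, cmb_deep, cmb_lobar, lac_deep, lac_lobar):
    pts = 0
    if lac_deep >= 1:
        pts += 1
    if cmb_deep >= 1:
        pts += 1
    if epvs_bg >= 2:
        pts += 1
    if deep_faz >= 2:
        pts += 1
    return pts


def oracle_global(pv_faz, deep_faz, epvs_bg, epvs_cso, cmb_deep, cmb_lobar, lac_deep, lac_lobar):
    pts = 0
    if lac_deep >= 1 or lac_lobar >= 1:
        pts += 1
    if cmb_deep >= 1 or cmb_lobar >= 1:
        pts += 1
    if epvs_bg >= 2:
        pts += 1
    if pv_faz == 3 or deep_faz >= 2:
        pts += 1
    return pts


def all_rating_combinations():
    """All 4*4*5*5*2*2*2*2 = 6400 admissible rating vectors."""
    for pv in range(4):
        for dp in range(4):
            for bg in range(5):
                for cso in range(5):
                    for cd in range(2):
                        for cl in range(2):
                            for ld in range(2):
                                for ll in range(2):
                                    yield (pv, dp, bg, cso, cd, cl, ld, ll)


def oracle_epvs_bin(count: int) -> int:
    if count == 0:
        return 0
    if 1 <= count <= 10:
        return 1
    if 11 <= count <= 20:
        return 2
    if 21 <= count <= 40:
        return 3
    return 4


def oracle_bh(p):
    """Literal Benjamini-Hochberg step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


def oracle_spearman_rho(x, y):
    """Pearson correlation of midranks."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        r = np.empty_like(v)
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            r[i] = less + (equal + 1) / 2.0
        return r

    rx, ry = midranks(x), midranks(y)
    return float(
        np.sum((rx - rx.mean()) * (ry - ry.mean()))
        / np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
    )


def oracle_kappa(table):
    t = np.asarray(table, dtype=float)
    n = t.sum()
    po = sum(t[i, i] for i in range(t.shape[0])) / n
    pe = sum(t[i, :].sum() * t[:, i].sum() for i in range(t.shape[0])) / n**2
    return (po - pe) / (1 - pe)
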