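#!/usr/bin/env python
"""Compute composite SVD scores and modifiable-risk scores for the cohort.

Reads results/cohort.csv (run 01 first), derives the three composite SVD
scores (global, CAA, hypertensive arteriopathy), dichotomises the six
Lancet-2020 risk factors at their published cut-offs, and reports the
risk-flag distribution.
"""

from pathlib import Path

import pandas as pd

from svdrisk import scoring
from svdrisk.pipeline import _prepare
from svdrisk.risk import add_risk_columns, risk_factor_distribution

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = _prepare(pd.read_csv(OUT / "cohort.csv"))
    scores = scoring.score_cohort(cohort)
    cohort = add_risk_columns(pd.concat([cohort, scores], axis=1))
    cohort.to_csv(OUT / "cohort_scored.csv", index=False)
    dist = risk_factor_distribution(cohort["n_risk_flags"])
    dist.to_csv(OUT / "risk_factor_distribution.csv")
    print("Composite score means (0-4 scales):")
    for col in ("global_svd", "caa", "hypertensive_arteriopathy"):
        s = pd.to_numeric(cohort[col], errors="coerce")
        print(f"  {col:26s} {s.mean():.2f} (SD {s.std():.2f}, missing {s.isna().sum()})")
    print("\nSubjects by number of positive risk flags (0 / 1 / 2 / 3+):")
    print("  " + " / ".join(f"{100*v:.1f}%" for v in dist))
    print(f"\nscored cohort -> {OUT/'cohort_scored.csv'}")


if __name__ == "__main__":
    main()
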