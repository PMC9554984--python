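#!/usr/bin/env python
"""Validate the WMH volumetric chain on a synthetic phantom.

Plants spherical lesions of known size in an ellipsoidal brain, segments
them at 1.2x the median brain intensity, splits periventricular vs deep at
a 10 mm boundary, and normalises volumes by TIV — reporting recovery
against ground truth with and without intensity noise.
"""

import json
from pathlib import Path

import numpy as np

from svdrisk.wmh import make_phantom, measure_wmh, segment_wmh

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    lesions = [((16, 16, 30), 2.5), ((32, 32, 24), 3.0), ((24, 12, 22), 2.0)]
    vol, truth = make_phantom(shape=(48, 48, 48), lesion_spec=lesions, seed=0)
    res = measure_wmh(vol, boundary_mm=10.0)
    exact = bool(np.array_equal(res.wmh_mask, truth))

    noisy, _ = make_phantom(shape=(48, 48, 48), lesion_spec=lesions, seed=0, noise_sd=0.05)
    got = segment_wmh(noisy)
    sens = float((got & truth).sum() / truth.sum())
    fp = int((got & ~truth).sum())

    report = {
        "planted_voxels": int(truth.sum()),
        "noise_free_exact_recovery": exact,
        "volume_total_ml": res.volume_total_ml,
        "volume_pv_ml": res.volume_pv_ml,
        "volume_deep_ml": res.volume_deep_ml,
        "wmh_pct_tiv": res.wmh_pct_tiv,
        "wmh_cuberoot": res.wmh_cuberoot,
        "noisy_sensitivity": sens,
        "noisy_false_positive_voxels": fp,
    }
    (OUT / "wmh_phantom.json").write_text(json.dumps(report, indent=2))
    print(f"planted {report['planted_voxels']} lesion voxels; "
          f"noise-free recovery exact: {exact}")
    print(f"total {res.volume_total_ml:.3f} mL = PV {res.volume_pv_ml:.3f} + "
          f"deep {res.volume_deep_ml:.3f}; {res.wmh_pct_tiv:.3f}% of TIV "
          f"(cube root {res.wmh_cuberoot:.3f})")
    print(f"with 5% noise: sensitivity {sens:.3f}, {fp} false-positive voxels")


if __name__ == "__main__":
    main()
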