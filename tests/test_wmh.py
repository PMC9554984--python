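"""WMH volumetrics: segmentation, PV/deep split, normalisation, phantom."""

import numpy as np
import pytest

from svdrisk.wmh import (
    BrainVolume,
    make_phantom,
    measure_wmh,
    normalize_and_transform,
    segment_wmh,
    split_pv_deep,
)


def test_uniform_brain_segments_nothing():
    vol, truth = make_phantom(shape=(24, 24, 24))
    assert not truth.any()
    assert not segment_wmh(vol).any()


def test_planted_lesions_recovered_exactly():
    spec = [((12, 12, 20), 2.0), ((30, 30, 24), 3.0), ((24, 14, 24), 1.0)]
    vol, truth = make_phantom(shape=(48, 48, 48), lesion_spec=spec)
    got = segment_wmh(vol)
    assert np.array_equal(got, truth)
    assert truth.sum() > 0


def test_segmentation_scale_invariance():
    vol, truth = make_phantom(shape=(32, 32, 32), lesion_spec=[((16, 16, 24), 2.5)])
    scaled = BrainVolume(
        vol.intensities * 7.3, vol.voxel_size, vol.brain_mask, vol.ventricle_mask
    )
    assert np.array_equal(segment_wmh(vol), segment_wmh(scaled))


def test_segmentation_empty_brain_errors():
    z = np.zeros((4, 4, 4))
    vol = BrainVolume(z, (1, 1, 1), np.zeros_like(z, bool), np.zeros_like(z, bool))
    with pytest.raises(ValueError, match="empty"):
        segment_wmh(vol)


def test_split_matches_bruteforce_distance_oracle():
    rng = np.random.default_rng(4)
    shape = (14, 12, 10)
    voxel = (1.0, 1.5, 2.0)  # anisotropic
    vent = np.zeros(shape, bool)
    vent[6:8, 5:7, 4:6] = True
    wmh = rng.random(shape) < 0.15
    pv, deep = split_pv_deep(wmh, vent, voxel, boundary_mm=6.0)
    # brute-force nearest ventricular voxel in mm
    vcoords = np.argwhere(vent).astype(float) * np.asarray(voxel)
    for idx in np.argwhere(wmh):
        d = np.sqrt(((vcoords - idx * np.asarray(voxel)) ** 2).sum(axis=1)).min()
        assert pv[tuple(idx)] == (d <= 6.0)
        assert deep[tuple(idx)] == (d > 6.0)
    assert not (pv & deep).any()
    assert np.array_equal(pv | deep, wmh)


def test_split_degenerate_cases():
    shape = (8, 8, 8)
    wmh = np.zeros(shape, bool)
    wmh[1, 1, 1] = True
    vent = np.zeros(shape, bool)
    vent[1, 1, 2] = True
    pv, deep = split_pv_deep(wmh, vent, (1, 1, 1), boundary_mm=10)
    assert pv[1, 1, 1] and not deep.any()  # adjacent voxel is periventricular
    pv0, deep0 = split_pv_deep(wmh, vent, (1, 1, 1), boundary_mm=0)
    assert not pv0.any() and deep0[1, 1, 1]  # zero boundary -> all deep
    with pytest.warns(UserWarning, match="ventricle mask empty"):
        pvE, deepE = split_pv_deep(wmh, np.zeros(shape, bool), (1, 1, 1))
    assert not pvE.any() and deepE[1, 1, 1]


def test_far_voxel_is_deep():
    shape = (40, 8, 8)
    vent = np.zeros(shape, bool)
    vent[0, 4, 4] = True
    wmh = np.zeros(shape, bool)
    wmh[20, 4, 4] = True  # 20 mm away at 1 mm isotropic
    pv, deep = split_pv_deep(wmh, vent, (1, 1, 1), boundary_mm=10)
    assert deep[20, 4, 4] and not pv.any()


def test_dilation_mode_marks_connected_halo():
    shape = (12, 12, 12)
    vent = np.zeros(shape, bool)
    vent[6, 6, 6] = True
    wmh = np.ones(shape, bool)
    pv, deep = split_pv_deep(wmh, vent, (1, 1, 1), method="dilation", dilation_iterations=4)
    # 6-connected dilation x4 = city-block ball of radius 4
    grid = np.indices(shape).reshape(3, -1).T
    cb = np.abs(grid - 6).sum(axis=1).reshape(shape)
    assert np.array_equal(pv, cb <= 4)


def test_normalise_and_transform_arithmetic():
    assert normalize_and_transform(0, 1000, 0.001) == (0.0, 0.0)
    pct, cr = normalize_and_transform(1, 1000, 0.001)
    assert pct == pytest.approx(0.1)
    assert cr == pytest.approx(0.1 ** (1 / 3))
    a = normalize_and_transform(50, 5000, 0.002)
    b = normalize_and_transform(100, 10000, 0.002)
    assert a == pytest.approx(b)  # scale invariance of the percentage
    with pytest.raises(ValueError):
        normalize_and_transform(1, 0, 0.001)


def test_measure_wmh_volume_conservation():
    spec = [((24, 24, 30), 2.0), ((10, 24, 24), 2.0)]
    vol, truth = make_phantom(shape=(48, 48, 48), voxel_size=(1.0, 1.0, 1.2), lesion_spec=spec)
    les = measure_wmh(vol, boundary_mm=8.0)
    assert les.volume_total_ml == pytest.approx(les.volume_pv_ml + les.volume_deep_ml)
    assert les.volume_total_ml == pytest.approx(truth.sum() * np.prod([1, 1, 1.2]) / 1000)
    assert les.wmh_pct_tiv == pytest.approx(100 * truth.sum() / vol.brain_mask.sum())
    assert les.wmh_cuberoot == pytest.approx(les.wmh_pct_tiv ** (1 / 3))


def test_phantom_construction_contract():
    vol, truth = make_phantom(lesion_spec=[((24, 24, 30), 2.0)])
    assert truth.sum() > 0
    assert not (truth & ~vol.brain_mask).any()
    with pytest.raises(ValueError, match="outside the brain"):
        make_phantom(shape=(24, 24, 24), lesion_spec=[((0, 0, 0), 2.0)])
    with pytest.raises(ValueError, match="contained in brain"):
        BrainVolume(
            np.zeros((4, 4, 4)),
            (1, 1, 1),
            np.zeros((4, 4, 4), bool),
            np.ones((4, 4, 4), bool),
        )


def test_noisy_phantom_recovery_rate():
    """With 5% Gaussian background noise, >= 99% of planted voxels recovered."""
    spec = [((24, 24, 32), 3.0), ((14, 30, 24), 3.0)]
    vol, truth = make_phantom(shape=(48, 48, 48), lesion_spec=spec, noise_sd=0.05, seed=2)
    got = segment_wmh(vol)
    sens = (got & truth).sum() / truth.sum()
    assert sens >= 0.99
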