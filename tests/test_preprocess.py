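import itertools
import logging

import nibabel as nib
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triplenet import (
    NodeSpec,
    SimulationConfig,
    bandpass_filter,
    detrend_linear,
    discard_initial_volumes,
    extract_cohort,
    extract_node_series,
    mni_to_voxel,
    preprocess_series,
    render_synthetic_volume,
    simulate_cohort,
    sphere_mask,
)


# ---------------------------------------------------------------- geometry

def test_mni_to_voxel_identity_affine():
    assert mni_to_voxel([10, -20, 30], np.eye(4)) == pytest.approx([10, -20, 30])


def test_mni_to_voxel_round_trip_2mm():
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-90, -126, -72]
    vox = np.array([45.0, 63.0, 36.0])
    mm = affine[:3, :3] @ vox + affine[:3, 3]
    assert mni_to_voxel(mm, affine) == pytest.approx(vox, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(min_value=0, max_value=10_000))
def test_mni_to_voxel_inverts_forward_map(seed):
    """For any invertible affine, voxel -> mm -> voxel is the identity."""
    rng = np.random.default_rng(seed)
    affine = np.eye(4)
    affine[:3, :3] = rng.normal(size=(3, 3)) + 3 * np.eye(3)
    affine[:3, 3] = rng.normal(scale=50, size=3)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-3:
        return
    vox = rng.uniform(-40, 40, size=3)
    mm = affine[:3, :3] @ vox + affine[:3, 3]
    assert np.allclose(mni_to_voxel(mm, affine), vox, atol=1e-9)


def test_mni_to_voxel_singular_affine():
    bad = np.zeros((4, 4))
    bad[3, 3] = 1.0
    with pytest.raises(ValueError, match="singular"):
        mni_to_voxel([0, 0, 0], bad)


def test_sphere_mask_1mm_isotropic_count():
    """3 mm ball on a 1 mm grid centred on a voxel holds 123 voxel centres."""
    node = NodeSpec("ctr", "N", 10, 10, 10, radius=3)
    mask = sphere_mask(node, np.eye(4), (21, 21, 21))
    assert len(mask) == 123  # |{v in Z^3 : |v|^2 <= 9}|


def test_sphere_mask_matches_bruteforce_on_anisotropic_grid():
    affine = np.diag([3.0, 3.0, 3.5, 1.0])
    affine[:3, 3] = [-15, -12, -10]
    shape = (11, 11, 9)
    node = NodeSpec("n", "N", 1.0, -2.0, 3.0, radius=4.0)
    expected = {
        (i, j, k)
        for i, j, k in itertools.product(*(range(s) for s in shape))
        if np.linalg.norm(affine[:3, :3] @ [i, j, k] + affine[:3, 3] - node.coords) <= node.radius
    }
    mask = sphere_mask(node, affine, shape)
    assert {tuple(v) for v in mask} == expected


def test_sphere_mask_empty_raises_naming_node():
    # 3.5 mm spacing, node between voxel centres, radius 1 mm: no centre inside
    affine = np.diag([3.5, 3.5, 3.5, 1.0])
    node = NodeSpec("thin", "N", 1.75, 1.75, 1.75, radius=1.0)
    with pytest.raises(ValueError, match="thin"):
        sphere_mask(node, affine, (10, 10, 10))


def test_sphere_mask_independent_of_time_axis():
    node = NodeSpec("n", "N", 5, 5, 5, radius=3)
    a = sphere_mask(node, np.eye(4), (11, 11, 11))
    b = sphere_mask(node, np.eye(4), (11, 11, 11, 999))  # extra dims ignored
    assert np.array_equal(a, b)


def test_extract_single_voxel_and_symmetry(rng):
    vol = rng.normal(size=(4, 4, 4, 7))
    one = extract_node_series(vol, np.array([[1, 2, 3]]))
    assert np.array_equal(one, vol[1, 2, 3, :])
    s = rng.normal(size=7)
    vol[0, 0, 0, :] = s
    vol[0, 0, 1, :] = -s
    both = extract_node_series(vol, np.array([[0, 0, 0], [0, 0, 1]]))
    assert np.allclose(both, 0.0, atol=1e-12)


def test_extract_matches_loop_oracle(rng):
    vol = rng.normal(size=(6, 5, 4, 9))
    mask = np.array([[0, 0, 0], [5, 4, 3], [2, 2, 2], [1, 0, 3], [3, 3, 1]])
    expected = sum(vol[i, j, k, :] for i, j, k in mask) / len(mask)
    assert np.allclose(extract_node_series(vol, mask), expected, atol=1e-12)


def test_extract_out_of_bounds_rejected(rng):
    vol = rng.normal(size=(3, 3, 3, 2))
    with pytest.raises(ValueError, match="out-of-bounds"):
        extract_node_series(vol, np.array([[0, 0, 3]]))


# ---------------------------------------------------------------- temporal

def test_discard_initial_volumes():
    x = np.arange(240.0)
    assert discard_initial_volumes(x).shape == (230,)
    assert np.array_equal(discard_initial_volumes(x, 0), x)
    assert discard_initial_volumes(x, 239).shape == (1,)
    with pytest.raises(ValueError):
        discard_initial_volumes(x, 240)
    vol = np.zeros((2, 2, 2, 240))
    assert discard_initial_volumes(vol).shape == (2, 2, 2, 230)


def test_detrend_removes_exact_line():
    t = np.arange(100.0)
    assert np.allclose(detrend_linear(2.0 + 0.5 * t), 0.0, atol=1e-10)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    st.floats(-100, 100, allow_nan=False),
    st.floats(-10, 10, allow_nan=False),
    st.integers(min_value=0, max_value=1000),
)
def test_detrend_invariant_to_added_line(a, b, seed):
    t = np.arange(64.0)
    x = np.random.default_rng(seed).normal(size=64)
    assert np.allclose(detrend_linear(x + a + b * t), detrend_linear(x), atol=1e-7)


def test_detrend_output_orthogonal_to_trend_basis(rng):
    x = rng.normal(size=201)
    out = detrend_linear(x)
    t = np.arange(201.0)
    assert abs(out.sum()) < 1e-9
    assert abs(out @ (t - t.mean())) / len(t) < 1e-9


def test_detrend_too_short():
    with pytest.raises(ValueError):
        detrend_linear(np.array([1.0, 2.0]))


def test_bandpass_removes_constant():
    out = bandpass_filter(np.full(230, 7.3), tr_seconds=2.0)
    assert np.allclose(out, 0.0, atol=1e-12)


def test_bandpass_preserves_in_band_sinusoid():
    t = np.arange(512) * 2.0
    x = np.sin(2 * np.pi * 0.04 * t)
    out = bandpass_filter(x, tr_seconds=2.0)
    # amplitude via sqrt(2) * RMS: robust to off-grid spectral leakage
    assert abs(np.sqrt(2 * (out**2).mean()) - np.sqrt(2 * (x**2).mean())) < 0.01
    # an exactly on-grid in-band tone passes through untouched
    x_grid = np.sin(2 * np.pi * (41 / 1024) * t)
    assert np.allclose(bandpass_filter(x_grid, 2.0), x_grid, atol=1e-12)


def test_bandpass_rejects_out_of_band_sinusoid():
    # on-grid frequency: 205 / (512 * 2 s) ~ 0.2002 Hz, well above the band
    t = np.arange(512) * 2.0
    x = np.sin(2 * np.pi * (205 / 1024) * t)
    out = bandpass_filter(x, tr_seconds=2.0)
    assert np.sqrt((out**2).mean()) < 1e-8 * np.sqrt((x**2).mean())


def test_bandpass_idempotent(rng):
    x = rng.normal(size=(3, 230))
    once = bandpass_filter(x, 2.0)
    assert np.allclose(bandpass_filter(once, 2.0), once, atol=1e-8)


def test_bandpass_validates_band():
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass_filter(np.zeros(100), tr_seconds=2.0, high_hz=0.25)
    with pytest.raises(ValueError):
        bandpass_filter(np.zeros(100), tr_seconds=2.0, low_hz=0.08, high_hz=0.01)


def test_preprocessing_commutes_with_spatial_averaging(rng):
    """Detrend + band-pass are linear, so filter-then-average equals
    average-then-filter over a mask."""
    vol = rng.normal(size=(5, 5, 5, 120))
    mask = np.array([[0, 1, 2], [3, 3, 3], [4, 0, 1], [2, 2, 0]])
    avg_first = preprocess_series(extract_node_series(vol, mask), 2.0)
    voxels = vol[mask[:, 0], mask[:, 1], mask[:, 2], :]
    filt_first = preprocess_series(voxels, 2.0).mean(axis=0)
    assert np.allclose(avg_first, filt_first, atol=1e-8)


# ---------------------------------------------------------------- cohort I/O

def _write_volume_cohort(tmp_path, tiny_atlas, n_timepoints=60, with_trend=False):
    cfg = SimulationConfig(
        n_per_group=2, n_timepoints=n_timepoints, seed=5, rai_effect=0.0, dmn_cen_effect=0.0
    )
    cohort = simulate_cohort(tiny_atlas, cfg)[:2]
    records = []
    for subj in cohort:
        if with_trend:
            subj.data = subj.data + 3.0 + 0.01 * np.arange(n_timepoints)
        data, affine = render_synthetic_volume(subj, tiny_atlas, background_noise_sd=0.0)
        img = nib.Nifti1Image(data.astype(np.float32), affine)
        img.header.set_zooms((2.0, 2.0, 2.0, 2.0))
        fname = f"{subj.subject_id}.nii"
        nib.save(img, str(tmp_path / fname))
        records.append({"subject_id": subj.subject_id, "group": subj.group, "file": fname})
    manifest = tmp_path / "manifest.tsv"
    pd.DataFrame(records).to_csv(manifest, sep="\t", index=False)
    return manifest, cohort


def test_extract_cohort_round_trip(tmp_path, tiny_atlas):
    """Zero-background rendering then extraction recovers each node's
    series up to the shared discard + detrend + band-pass."""
    manifest, cohort = _write_volume_cohort(tmp_path, tiny_atlas)
    out = extract_cohort(manifest, tiny_atlas, tr_seconds=2.0, discard=10)
    for recovered, original in zip(out, cohort):
        expected = preprocess_series(original.data[:, 10:], 2.0)
        # float32 NIfTI storage costs ~1e-7 relative precision
        assert np.allclose(recovered.data, expected, atol=1e-4)
        for row_rec, row_exp in zip(recovered.data, expected):
            assert np.corrcoef(row_rec, row_exp)[0, 1] > 0.9999


def test_extract_cohort_missing_file(tmp_path, tiny_atlas):
    manifest = tmp_path / "manifest.tsv"
    pd.DataFrame([{"subject_id": "s1", "group": "g", "file": "absent.nii"}]).to_csv(
        manifest, sep="\t", index=False
    )
    with pytest.raises(FileNotFoundError, match="absent.nii"):
        extract_cohort(manifest, tiny_atlas)


def test_extract_cohort_header_tr_mismatch_logs_and_config_wins(tmp_path, tiny_atlas, caplog):
    manifest, cohort = _write_volume_cohort(tmp_path, tiny_atlas)
    with caplog.at_level(logging.WARNING, logger="triplenet.preprocess"):
        out = extract_cohort(manifest, tiny_atlas, tr_seconds=1.5, discard=10)
    assert any("header TR" in rec.message for rec in caplog.records)
    assert out[0].tr_seconds == 1.5
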