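import numpy as np
import pytest

from triplenet import (
    GROUP_AFFECTED,
    GROUP_CONTROL,
    NetworkAtlas,
    NodeSpec,
    SimulationConfig,
    build_target_correlation,
    connectivity_matrix,
    node_degree,
    render_synthetic_volume,
    repair_correlation,
    simulate_cohort,
    simulate_subject_series,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_per_group=1)
    with pytest.raises(ValueError):
        SimulationConfig(ar_phi=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(within_network_r=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(noise_sd=-0.1)


def test_null_config_gives_identical_group_targets(atlas):
    tgt = build_target_correlation(atlas, SimulationConfig(rai_effect=0.0, dmn_cen_effect=0.0))
    assert np.array_equal(tgt.matrix(GROUP_CONTROL), tgt.matrix(GROUP_AFFECTED))


def test_target_block_structure(atlas):
    """Control matrix: 0.5 within networks, 0.1 across, unit diagonal."""
    cfg = SimulationConfig(within_network_r=0.5, between_network_r=0.1)
    tgt = build_target_correlation(atlas, cfg)
    c = tgt.matrix(GROUP_CONTROL)
    dmn = atlas.network_indices("DMN")
    cen = atlas.network_indices("CEN")
    block = c[np.ix_(dmn, dmn)]
    assert np.allclose(block[~np.eye(4, dtype=bool)], 0.5)
    assert np.allclose(c[np.ix_(dmn, cen)], 0.1)
    assert np.allclose(np.diag(c), 1.0)


def test_target_planted_effects(atlas):
    cfg = SimulationConfig()
    tgt = build_target_correlation(atlas, cfg)
    ctrl, aff = tgt.matrix(GROUP_CONTROL), tgt.matrix(GROUP_AFFECTED)
    k = atlas.index("rAI")
    dmn = atlas.network_indices("DMN")
    cen = atlas.network_indices("CEN")
    # directions survive the positive-definite repair
    assert (aff[k, dmn] > ctrl[k, dmn]).all()
    assert (aff[np.ix_(dmn, cen)] < ctrl[np.ix_(dmn, cen)]).all()
    assert np.linalg.eigvalsh(aff).min() > 0
    assert tgt.max_repair_delta[GROUP_AFFECTED] < 0.05


def test_rai_effect_requires_rai_node(tiny_atlas):
    with pytest.raises(ValueError, match="rAI"):
        build_target_correlation(tiny_atlas, SimulationConfig(rai_effect=0.2, dmn_cen_effect=0.0))


def test_repair_of_deliberately_non_pd_target():
    """Three nodes with all pairwise r = -0.9 cannot be a correlation
    matrix; repair must return a unit-diagonal PD matrix."""
    bad = np.full((3, 3), -0.9)
    np.fill_diagonal(bad, 1.0)
    assert np.linalg.eigvalsh(bad).min() < 0  # oracle: genuinely non-PD
    fixed = repair_correlation(bad)
    assert np.linalg.eigvalsh(fixed).min() > 0
    assert np.allclose(np.diag(fixed), 1.0, atol=1e-12)
    assert np.allclose(fixed, fixed.T, atol=1e-12)
    assert np.abs(fixed - bad).max() > 0.1  # a real repair, not a no-op


def test_subject_series_deterministic():
    cfg = SimulationConfig(n_timepoints=50)
    tgt = np.eye(3)
    a = simulate_subject_series(tgt, cfg, subject_seed=42)
    b = simulate_subject_series(tgt, cfg, subject_seed=42)
    assert np.array_equal(a.data, b.data)
    c = simulate_subject_series(tgt, cfg, subject_seed=43)
    assert not np.array_equal(a.data, c.data)


def test_identity_target_gives_near_zero_correlations():
    cfg = SimulationConfig(n_timepoints=10_000, ar_phi=0.0, noise_sd=0.0)
    subj = simulate_subject_series(np.eye(5), cfg, subject_seed=1)
    c = np.corrcoef(subj.data)
    off = c[~np.eye(5, dtype=bool)]
    assert np.abs(off).max() < 0.05


@pytest.mark.parametrize("phi", [0.0, 0.3])
def test_two_node_target_correlation_recovered(phi):
    """With no measurement noise the empirical correlation matches the
    target for any AR coefficient (mixing happens after the AR step)."""
    cfg = SimulationConfig(n_timepoints=10_000, ar_phi=phi, noise_sd=0.0)
    tgt = np.array([[1.0, 0.8], [0.8, 1.0]])
    subj = simulate_subject_series(tgt, cfg, subject_seed=3)
    c = np.corrcoef(subj.data)[0, 1]
    assert abs(c - 0.8) < 0.03 if phi == 0.0 else abs(c - 0.8) < 0.05


def test_non_pd_target_rejected():
    bad = np.full((3, 3), -0.9)
    np.fill_diagonal(bad, 1.0)
    with pytest.raises(ValueError, match="positive definite"):
        simulate_subject_series(bad, SimulationConfig(), subject_seed=0)


def test_cohort_counts_labels_and_determinism(atlas):
    cfg = SimulationConfig(n_per_group=4, n_timepoints=40, seed=9)
    cohort = simulate_cohort(atlas, cfg)
    assert len(cohort) == 8
    assert sum(s.group == GROUP_CONTROL for s in cohort) == 4
    assert sum(s.group == GROUP_AFFECTED for s in cohort) == 4
    assert [s.subject_id for s in cohort[:2]] == ["control_1", "control_2"]
    again = simulate_cohort(atlas, cfg)
    for a, b in zip(cohort, again):
        assert a.subject_id == b.subject_id
        assert np.array_equal(a.data, b.data)


def test_rai_degree_increases_with_planted_effect(atlas):
    """Expected degree of rAI in the affected group grows monotonically
    with the planted coupling increment."""
    means = []
    for effect in (0.0, 0.15, 0.3):
        cfg = SimulationConfig(n_per_group=8, n_timepoints=200, seed=21, rai_effect=effect)
        cohort = simulate_cohort(atlas, cfg)
        k = atlas.index("rAI")
        gammas = [
            node_degree(connectivity_matrix(s))[k] for s in cohort if s.group == GROUP_AFFECTED
        ]
        means.append(np.mean(gammas))
    assert means[0] < means[1] < means[2]


# ---------------------------------------------------------------- rendering

def test_render_round_trip_exact(tiny_atlas):
    cfg = SimulationConfig(n_per_group=2, n_timepoints=30, seed=2, rai_effect=0.0, dmn_cen_effect=0.0)
    subj = simulate_cohort(tiny_atlas, cfg)[0]
    data, affine = render_synthetic_volume(subj, tiny_atlas, background_noise_sd=0.0)
    from triplenet import extract_node_series, sphere_mask

    for i, node in enumerate(tiny_atlas):
        mask = sphere_mask(node, affine, data.shape[:3])
        assert len(mask) >= 7
        recovered = extract_node_series(data, mask)
        assert np.allclose(recovered, subj.data[i], atol=1e-12)


def test_render_background_noise_does_not_corrupt_spheres(tiny_atlas):
    cfg = SimulationConfig(n_per_group=2, n_timepoints=230, seed=4, rai_effect=0.0, dmn_cen_effect=0.0)
    subj = simulate_cohort(tiny_atlas, cfg)[0]
    data, affine = render_synthetic_volume(subj, tiny_atlas, background_noise_sd=1.0, seed=8)
    from triplenet import extract_node_series, sphere_mask

    for i, node in enumerate(tiny_atlas):
        recovered = extract_node_series(data, sphere_mask(node, affine, data.shape[:3]))
        assert np.corrcoef(recovered, subj.data[i])[0, 1] > 0.99
    # background really is noisy
    assert data.std() > 0


def test_render_overlapping_spheres_rejected():
    close = NetworkAtlas(
        [NodeSpec("p", "N1", 0, 0, 0, radius=3), NodeSpec("q", "N2", 2, 0, 0, radius=3)]
    )
    cfg = SimulationConfig(n_per_group=2, n_timepoints=10, seed=0, rai_effect=0.0, dmn_cen_effect=0.0)
    subj = simulate_cohort(close, cfg)[0]
    with pytest.raises(ValueError, match="overlap"):
        render_synthetic_volume(subj, close)


def test_render_determinism(tiny_atlas):
    cfg = SimulationConfig(n_per_group=2, n_timepoints=15, seed=6, rai_effect=0.0, dmn_cen_effect=0.0)
    subj = simulate_cohort(tiny_atlas, cfg)[0]
    a, _ = render_synthetic_volume(subj, tiny_atlas, background_noise_sd=0.5, seed=12)
    b, _ = render_synthetic_volume(subj, tiny_atlas, background_noise_sd=0.5, seed=12)
    assert np.array_equal(a, b)
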