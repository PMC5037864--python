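"""Surface extraction, distance measurement and the pooled Gaussian fit."""

import numpy as np
import pytest

from qdepth import (
    DepthFitResult,
    SegmentedObject,
    VoxelSpacing,
    classify_penetration,
    extract_apical_surface,
    measure_distance,
    pool_and_fit,
)


def _particle_at(com_um, oid=1, voxels=500):
    return SegmentedObject(
        object_id=oid,
        voxel_count=voxels,
        com_um=tuple(com_um),
        intensity_max=100.0,
        intensity_mean=50.0,
        bounding_box=((0, 1), (0, 1), (0, 1)),
    )


# --- surface extraction -----------------------------------------------------


def test_flat_slab_surface_is_its_top_plane(spacing):
    mask = np.zeros((32, 16, 16), bool)
    mask[10:13, 2:14, 3:12] = True
    ref = extract_apical_surface(mask, spacing)
    inside = ~np.isnan(ref.surface_map_um)
    assert inside.sum() == 12 * 9
    assert np.allclose(ref.surface_map_um[inside], 10 * spacing.dz)
    # no membrane voxel sits apically above any surface voxel in its column
    for z, y, x in ref.surface_voxels:
        assert not mask[:z, y, x].any()


def test_tilted_slab_surface_reproduces_the_tilt(spacing):
    mask = np.zeros((32, 16, 40), bool)
    for x in range(40):
        top = 8 + x // 10  # one-voxel rise every 10 columns
        mask[top : top + 3, :, x] = True
    ref = extract_apical_surface(mask, spacing)
    for x in range(40):
        assert ref.surface_map_um[0, x] == pytest.approx((8 + x // 10) * spacing.dz)


def test_surface_map_is_never_extrapolated(spacing):
    mask = np.zeros((16, 16, 16), bool)
    mask[5, 4:8, 4:8] = True
    ref = extract_apical_surface(mask, spacing)
    assert np.isnan(ref.surface_map_um[0, 0])
    assert np.isnan(ref.surface_map_um).sum() == 16 * 16 - 16


def test_empty_mask_is_rejected(spacing):
    with pytest.raises(ValueError):
        extract_apical_surface(np.zeros((8, 8, 8), bool), spacing)


# --- distance measurement ---------------------------------------------------


def _flat_reference(spacing, z_plane=15):
    mask = np.zeros((32, 24, 24), bool)
    mask[z_plane : z_plane + 3] = True
    return extract_apical_surface(mask, spacing)


def test_com_on_the_surface_measures_zero(spacing):
    ref = _flat_reference(spacing)
    rec = measure_distance(_particle_at((15 * spacing.dz, 0.6, 0.6)), ref)
    assert rec.axial_distance_um == 0.0


def test_com_below_a_flat_surface_measures_negative_depth(spacing):
    # 1.3 µm basal of the surface, directly under a surface voxel
    ref = _flat_reference(spacing)
    z = 15 * spacing.dz + 1.3
    rec = measure_distance(_particle_at((z, 0.6, 0.6)), ref, stack_id="s1")
    assert rec.axial_distance_um == pytest.approx(-1.3)
    assert rec.stack_id == "s1"


def test_distance_matches_brute_force_minimiser(rng, spacing):
    """Exhaustive oracle: scan every surface voxel, take the 3D-nearest,
    project its offset onto z."""
    dzyx = np.array(spacing.zyx)
    for _ in range(25):
        n = rng.integers(5, 1000)
        voxels = np.unique(
            np.column_stack(
                [
                    rng.integers(0, 30, n),
                    rng.integers(0, 24, n),
                    rng.integers(0, 24, n),
                ]
            ),
            axis=0,
        )
        mask = np.zeros((32, 24, 24), bool)
        mask[tuple(voxels.T)] = True
        # keep only apical-most per column, as the extractor does
        ref = extract_apical_surface(mask, spacing)
        com = rng.uniform((0, 0, 0), (31 * 0.2, 23 * 0.06, 23 * 0.06))
        rec = measure_distance(_particle_at(com), ref)

        pts = ref.surface_voxels * dzyx
        d2 = ((pts - com) ** 2).sum(axis=1)
        best = pts[np.argmin(d2)]
        assert rec.axial_distance_um == best[0] - com[0]
        assert rec.nearest_surface_point == tuple(best)


def test_axial_shift_equivariance(spacing):
    """Shifting scene and particle together changes nothing; shifting only the
    particle by k voxels changes the distance by exactly -k*dz."""
    ref = _flat_reference(spacing, z_plane=10)
    ref_shifted = _flat_reference(spacing, z_plane=13)
    com = np.array([10 * spacing.dz - 0.5, 0.72, 0.72])
    k = 3
    base = measure_distance(_particle_at(com), ref).axial_distance_um
    both = measure_distance(
        _particle_at(com + [k * spacing.dz, 0, 0]), ref_shifted
    ).axial_distance_um
    only_particle = measure_distance(
        _particle_at(com + [k * spacing.dz, 0, 0]), ref
    ).axial_distance_um
    assert both == base
    assert only_particle == base - k * spacing.dz


# --- pooled fit -------------------------------------------------------------


def test_gaussian_peak_recovery_from_large_normal_sample():
    rng = np.random.default_rng(0)
    fit = pool_and_fit(rng.normal(-1.3, 0.5, 5000), bin_width_um=0.2)
    assert fit.fit_ok
    assert abs(fit.x_c - (-1.3)) < max(3 * fit.x_c_se, 0.05)
    assert abs(fit.sigma_fit - 0.5) < 0.05
    assert fit.histogram[1].sum() == 5000


def test_near_zero_peak_is_resolved():
    # the membrane-associated regime: a population centred just above zero
    rng = np.random.default_rng(1)
    fit = pool_and_fit(rng.normal(0.03, 0.2, 1000), bin_width_um=0.2)
    assert fit.fit_ok
    assert abs(fit.x_c - 0.03) < 3 * max(fit.x_c_se, 0.2 / np.sqrt(1000))


def test_all_equal_distances_are_degenerate():
    fit = pool_and_fit(np.full(25, 0.25))
    assert fit.degenerate and not fit.fit_ok
    assert fit.x_c == 0.25
    assert fit.sigma_fit == 0.0


def test_thin_pools_are_refused():
    with pytest.raises(ValueError, match="at least 20"):
        pool_and_fit(np.zeros(19))


def test_pooling_is_order_invariant():
    rng = np.random.default_rng(3)
    d = rng.normal(-0.5, 0.3, 400)
    a = pool_and_fit(d)
    b = pool_and_fit(rng.permutation(d))
    assert np.array_equal(a.distances, b.distances)
    assert (a.x_c, a.sigma_fit, a.x_c_se) == (b.x_c, b.sigma_fit, b.x_c_se)
    assert np.array_equal(a.histogram[1], b.histogram[1])


def test_narrow_samples_get_a_refined_bin_width():
    rng = np.random.default_rng(4)
    fit = pool_and_fit(rng.normal(-1.3, 0.01, 200), bin_width_um=0.2)
    assert fit.bin_width_um < 0.2
    assert fit.fit_ok
    assert abs(fit.x_c - (-1.3)) < 0.01


def test_non_gaussian_pool_is_not_adopted():
    rng = np.random.default_rng(5)
    bimodal = np.concatenate([rng.normal(-1.3, 0.05, 300), rng.normal(0.4, 0.05, 300)])
    fit = pool_and_fit(bimodal)
    assert not fit.normal_ok and not fit.fit_ok
    assert np.isfinite(fit.median)


# --- classification ---------------------------------------------------------


def _result(x_c, se):
    d = np.sort(np.random.default_rng(0).normal(x_c, 0.3, 50))
    counts, edges = np.histogram(d, bins=10)
    centers = (edges[:-1] + edges[1:]) / 2
    return DepthFitResult(
        distances=d,
        bin_width_um=float(edges[1] - edges[0]),
        histogram=(centers, counts),
        x_c=x_c,
        x_c_se=se,
        sigma_fit=0.3,
        sigma_se=0.05,
        amplitude=10.0,
        fit_ok=True,
    )


@pytest.mark.parametrize(
    "x_c, se, verdict",
    [
        (-1.3, 0.1, "penetrating"),
        (0.03, 0.01, "membrane-associated"),
        (-0.05, 0.1, "membrane-associated"),  # negative but not significant
    ],
)
def test_verdict_follows_the_significance_rule(x_c, se, verdict):
    assert classify_penetration(_result(x_c, se)) == verdict


def test_classification_requires_a_valid_fit():
    res = _result(-1.3, 0.1)
    res.fit_ok = False
    with pytest.raises(ValueError):
        classify_penetration(res)
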