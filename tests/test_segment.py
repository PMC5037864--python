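"""Thresholding, labelling, object filters and watershed splitting."""

import numpy as np
import pytest

from qdepth import (
    MembraneNotFoundError,
    SceneSpec,
    SegmentationParams,
    SegmentedObject,
    SpotSpec,
    VoxelSpacing,
    equivalent_diameter,
    filter_membrane,
    filter_particles,
    label_objects,
    otsu_threshold,
    render_scene,
    watershed_split,
)

from conftest import NO_NOISE


def brute_force_otsu(data, nbins=256):
    """Independent oracle: try every split of the 256-bin histogram, computing
    the between-class variance exactly (Fractions over bin indices)."""
    from fractions import Fraction

    counts, edges = np.histogram(data, bins=nbins, range=(data.min(), data.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    idx = np.arange(nbins)
    best_t, best_v = None, Fraction(-1)
    for k in range(nbins - 1):
        w0, w1 = int(counts[: k + 1].sum()), int(counts[k + 1 :].sum())
        if w0 == 0 or w1 == 0:
            continue
        m0 = Fraction(int((counts[: k + 1] * idx[: k + 1]).sum()), w0)
        m1 = Fraction(int((counts[k + 1 :] * idx[k + 1 :]).sum()), w1)
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, centers[k]
    return best_t


def test_perfectly_bimodal_stack_is_split_correctly(rng):
    data = np.where(rng.uniform(size=(16, 16, 16)) < 0.5, 0.0, 200.0)
    t = otsu_threshold(data)
    assert ((data > t) == (data == 200.0)).all()


@pytest.mark.parametrize("seed", range(8))
def test_otsu_equals_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    data = rng.uniform(0, 100, (16, 16, 16))
    if seed % 2:
        data = np.round(data)  # integer-valued stacks hit histogram ties harder
    assert otsu_threshold(data) == brute_force_otsu(data)


def test_otsu_agrees_with_reference_library(rng):
    # the split can sit anywhere in an empty histogram gap, so compare the
    # induced foreground masks rather than the raw threshold values
    from skimage.filters import threshold_otsu

    data = rng.normal(50, 10, (16, 16, 16)).clip(0) + 200 * (
        rng.uniform(size=(16, 16, 16)) > 0.95
    )
    ours = data > otsu_threshold(data)
    theirs = data > threshold_otsu(data, nbins=256)
    assert np.array_equal(ours, theirs)


def test_constant_stack_has_no_threshold():
    with pytest.raises(ValueError, match="constant"):
        otsu_threshold(np.full((8, 8, 8), 7.0))


# --- labelling --------------------------------------------------------------


def test_two_disjoint_cubes_are_two_objects(spacing):
    data = np.zeros((16, 32, 32))
    data[2:5, 2:5, 2:5] = 10.0
    data[9:12, 20:23, 20:23] = 10.0
    objects, labels = label_objects(data, 5.0, spacing)
    assert len(objects) == 2
    assert sorted(o.voxel_count for o in objects) == [27, 27]


def test_symmetric_object_com_is_its_geometric_center(spacing):
    data = np.zeros((16, 32, 32))
    data[4:7, 10:13, 20:23] = 8.0  # cube centred at (5, 11, 21)
    objects, _ = label_objects(data, 1.0, spacing)
    (obj,) = objects
    assert obj.com_um == pytest.approx(
        (5 * spacing.dz, 11 * spacing.dy, 21 * spacing.dx)
    )
    assert obj.intensity_max == 8.0


def test_diagonally_touching_voxels_merge_under_26_connectivity(spacing):
    data = np.zeros((8, 32, 32))
    data[2, 2, 2] = 1.0
    data[3, 3, 3] = 1.0  # touches only at a corner
    objects, _ = label_objects(data, 0.5, spacing)
    assert len(objects) == 1
    assert objects[0].voxel_count == 2


def test_empty_foreground_yields_empty_list(spacing):
    objects, _ = label_objects(np.zeros((8, 32, 32)), 0.5, spacing)
    assert objects == []


# --- membrane filter --------------------------------------------------------


def _fake_object(oid, voxels):
    return SegmentedObject(
        object_id=oid,
        voxel_count=voxels,
        com_um=(1.0, 1.0, 1.0),
        intensity_max=100.0,
        intensity_mean=50.0,
        bounding_box=((4, 7), (0, 8), (0, 8)),
    )


def _labels_with(ids):
    labels = np.zeros((16, 32, 32), dtype=np.int32)
    for i, oid in enumerate(ids):
        labels[4:7, 8 * i : 8 * i + 8, :8] = oid
    return labels


def test_only_the_large_membrane_sheet_survives(spacing):
    params = SegmentationParams()
    objects = [_fake_object(1, 10**5 + 1), _fake_object(2, 5000)]
    ref = filter_membrane(objects, _labels_with([1, 2]), params, spacing)
    assert ref.object.object_id == 1


def test_membrane_volume_threshold_is_inclusive(spacing):
    params = SegmentationParams()
    objects = [_fake_object(1, 10**5)]
    ref = filter_membrane(objects, _labels_with([1]), params, spacing)
    assert ref.object.voxel_count == 10**5


def test_no_membrane_found_is_an_explicit_error(spacing):
    with pytest.raises(MembraneNotFoundError):
        filter_membrane(
            [_fake_object(1, 100), _fake_object(2, 100)],
            _labels_with([1, 2]),
            SegmentationParams(),
            spacing,
        )


def test_multiple_survivors_keep_largest_with_warning(spacing):
    objects = [_fake_object(1, 2 * 10**5), _fake_object(2, 10**5)]
    with pytest.warns(UserWarning, match="largest"):
        ref = filter_membrane(objects, _labels_with([1, 2]), SegmentationParams(), spacing)
    assert ref.object.object_id == 1


# --- particle filters -------------------------------------------------------


def _particle(oid, voxels, intensity_max):
    return SegmentedObject(
        object_id=oid,
        voxel_count=voxels,
        com_um=(1.0, 1.0, 1.0),
        intensity_max=intensity_max,
        intensity_mean=intensity_max / 2,
        bounding_box=((0, 1), (0, 1), (0, 1)),
    )


def test_particle_filters_apply_both_reference_rules():
    # threshold 100, global max 300 -> 5 % intensity cut at 110
    params = SegmentationParams()
    objects = [
        _particle(1, 449, 300.0),  # bright but one voxel too small
        _particle(2, 600, 100 + 0.04 * 200),  # big but below the 5 % cut
        _particle(3, 450, 100 + 0.05 * 200),  # exactly at both cuts: kept
        _particle(4, 600, 300.0),  # at the global maximum: kept
    ]
    kept = filter_particles(objects, 100.0, 300.0, params)
    assert [o.object_id for o in kept] == [3, 4]


def test_raising_volume_floor_never_adds_objects(rng):
    objects = [
        _particle(i, int(v), 200.0 + i)
        for i, v in enumerate(rng.integers(100, 2000, 40))
    ]
    kept_prev = None
    for floor in (100, 450, 900, 1500):
        params = SegmentationParams(qd_min_voxels=floor)
        kept = {o.object_id for o in filter_particles(objects, 100.0, 300.0, params)}
        if kept_prev is not None:
            assert kept <= kept_prev
        kept_prev = kept


# --- watershed --------------------------------------------------------------


def _merged_pair_scene():
    """Two PSF spots 0.6 µm apart that merge into one supra-threshold blob."""
    spec = SceneSpec(
        shape=(32, 64, 64),
        spacing=VoxelSpacing(),
        membrane_depth_um=3.0,
        spots=[
            SpotSpec(-1.0, 1.92 - 0.3, 1.92, amplitude=400.0),
            SpotSpec(-1.0, 1.92 + 0.3, 1.92, amplitude=400.0),
        ],
        seed=5,
    )
    return spec, render_scene(spec)


def test_watershed_splits_a_merged_pair(spacing):
    from qdepth import otsu_threshold, smooth_lateral

    spec, scene = _merged_pair_scene()
    smoothed = smooth_lateral(scene.particles.data, 2.0)
    thr = otsu_threshold(smoothed)
    mask = smoothed > thr
    objects, labels = watershed_split(smoothed, mask, 0.1, spacing)
    assert len(objects) == 2
    # volumes partition the mask exactly
    assert sum(o.voxel_count for o in objects) == int(mask.sum())
    true_y = sorted([1.62, 2.22])
    got_y = sorted(o.com_um[1] for o in objects)
    for got, want in zip(got_y, true_y):
        assert abs(got - want) <= 0.12


def test_single_spot_is_not_split(spacing):
    spec = SceneSpec(
        shape=(32, 64, 64),
        spacing=VoxelSpacing(),
        membrane_depth_um=3.0,
        spots=[SpotSpec(-1.0, 1.92, 1.92, amplitude=400.0)],
        noise=NO_NOISE,
    )
    scene = render_scene(spec)
    mask = scene.particles.data > 40.0
    objects, labels = watershed_split(scene.particles.data, mask, 0.1, spacing)
    assert len(objects) == 1
    assert objects[0].voxel_count == int(mask.sum())


def test_watershed_labels_partition_the_mask(rng, spacing):
    data = rng.uniform(0, 100, (16, 32, 32))
    mask = data > 60
    objects, labels = watershed_split(data, mask, 0.1, spacing)
    assert ((labels > 0) == mask).all()
    assert sum(o.voxel_count for o in objects) == int(mask.sum())


def test_empty_mask_is_rejected(spacing):
    with pytest.raises(ValueError):
        watershed_split(np.zeros((8, 32, 32)), np.zeros((8, 32, 32), bool), 0.1, spacing)


# --- equivalent diameter ----------------------------------------------------


def test_single_voxel_equivalent_diameter_closed_form(spacing):
    obj = _particle(1, 1, 10.0)
    v = 0.06 * 0.06 * 0.2
    assert equivalent_diameter(obj, spacing) == pytest.approx((6 * v / np.pi) ** (1 / 3))


def test_doubling_spacing_doubles_the_diameter():
    obj = _particle(1, 123, 10.0)
    d1 = equivalent_diameter(obj, VoxelSpacing(0.06, 0.06, 0.2))
    d2 = equivalent_diameter(obj, VoxelSpacing(0.12, 0.12, 0.4))
    assert d2 == pytest.approx(2 * d1)
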