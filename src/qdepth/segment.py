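"""Segmentation of membrane and particle channels.

Thresholds are computed by Otsu's method on a 256-bin histogram of each
channel's intensity range; supra-threshold voxels are grouped into
26-connected components; the membrane keeps only the single large sheet
(volume ≥ 10⁵ voxels), while particle objects must exceed the minimal volume
of a single quantum dot (450 voxels) *and* a minimal brightness (peak within
5 % of the threshold-to-maximum range).  Merged agglomerates are split by a
marker-based watershed on the Gaussian-smoothed intensity (σ = 0.1 µm).

All thresholds and filter floors are configurable; the defaults encode the
analysis conditions described above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .stack_io import VoxelSpacing, VoxelStack, _as_array

__all__ = [
    "SegmentedObject",
    "SegmentationParams",
    "MembraneNotFoundError",
    "otsu_threshold",
    "label_objects",
    "filter_membrane",
    "filter_particles",
    "watershed_split",
    "equivalent_diameter",
]

#: full 26-neighbourhood connectivity in 3D
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class MembraneNotFoundError(RuntimeError):
    """No segmented object large enough to be the apical membrane sheet."""


@dataclass(frozen=True)
class SegmentedObject:
    """One connected supra-threshold component with its summary statistics.

    ``com_um`` is the intensity-weighted centre of mass in µm, stack
    coordinates (z, y, x), voxel-centre based.
    """

    object_id: int
    voxel_count: int
    com_um: tuple[float, float, float]
    intensity_max: float
    intensity_mean: float
    bounding_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("an object has at least one voxel")


@dataclass(frozen=True)
class SegmentationParams:
    """Volume/intensity filters and watershed settings.

    ``seed_min_distance_px`` is the minimum lateral separation of watershed
    seeds; the default is one FWHM of the smoothed spot profile, which
    prevents noise-driven oversplitting of agglomerates while still
    separating spots ≥ 0.6 µm apart.
    """

    membrane_min_voxels: int = 100_000
    qd_min_voxels: int = 450
    qd_rel_intensity_min: float = 0.05
    watershed_sigma_um: float = 0.1
    seed_min_distance_px: int = 7

    def __post_init__(self) -> None:
        if self.membrane_min_voxels <= 0 or self.qd_min_voxels <= 0:
            raise ValueError("volume thresholds must be positive")
        if not 0 < self.qd_rel_intensity_min < 1:
            raise ValueError("relative intensity threshold must be in (0, 1)")
        if self.watershed_sigma_um <= 0:
            raise ValueError("watershed sigma must be positive")
        if self.seed_min_distance_px < 1:
            raise ValueError("seed separation must be >= 1 px")


def otsu_threshold(stack: "VoxelStack | np.ndarray", nbins: int = 256) -> float:
    """Threshold maximising between-class variance over a 256-bin histogram.

    The histogram spans the stack's min–max intensity range; the returned
    threshold is the centre of the optimal split bin, and foreground is
    ``intensity > threshold``.  The maximisation runs in exact integer
    arithmetic over bin indices (bin centres are affine in the index, and the
    between-class variance argmax is affine-invariant), so ties — exact
    plateaus occur whenever the split moves across empty bins — break
    deterministically on the first maximum instead of on float noise.
    A constant stack has no threshold and raises ``ValueError``.
    """
    data = _as_array(stack)
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise ValueError("constant stack: no threshold separates two classes")
    counts, edges = np.histogram(data, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0

    # sigma_b^2(k) = (S0*W - S*w0)^2 / (w0 * w1), all integers over bin indices
    total = int(counts.sum())
    index_sum = int((counts * np.arange(nbins)).sum())
    best_k, best_num, best_den = -1, -1, 1
    w0 = 0
    s0 = 0
    for k in range(nbins - 1):
        w0 += int(counts[k])
        s0 += int(counts[k]) * k
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (s0 * total - index_sum * w0) ** 2
        den = w0 * w1
        if num * best_den > best_num * den:  # exact fraction comparison
            best_k, best_num, best_den = k, num, den
    return float(centers[best_k])


def _objects_from_labels(
    data: np.ndarray,
    labels: np.ndarray,
    n: int,
    spacing: VoxelSpacing,
) -> list[SegmentedObject]:
    if n == 0:
        return []
    ids = np.arange(1, n + 1)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    maxima = ndi.maximum(data, labels, ids)
    means = ndi.mean(data, labels, ids)
    coms = ndi.center_of_mass(data, labels, ids)
    boxes = ndi.find_objects(labels)
    dz, dy, dx = spacing.zyx
    objs = []
    for i, oid in enumerate(ids):
        box = boxes[oid - 1]
        objs.append(
            SegmentedObject(
                object_id=int(oid),
                voxel_count=int(counts[i]),
                com_um=(coms[i][0] * dz, coms[i][1] * dy, coms[i][2] * dx),
                intensity_max=float(np.atleast_1d(maxima)[i]),
                intensity_mean=float(np.atleast_1d(means)[i]),
                bounding_box=tuple((s.start, s.stop) for s in box),
            )
        )
    return objs


def label_objects(
    stack: "VoxelStack | np.ndarray",
    threshold: float,
    spacing: VoxelSpacing | None = None,
) -> tuple[list[SegmentedObject], np.ndarray]:
    """26-connected components of the supra-threshold mask, with statistics.

    Returns the object list and the label image.  Centres of mass are
    intensity-weighted over each object's own voxels.  An empty foreground
    yields an empty list.
    """
    data = _as_array(stack)
    if spacing is None:
        spacing = stack.spacing if isinstance(stack, VoxelStack) else VoxelSpacing()
    labels, n = ndi.label(data > threshold, structure=STRUCT_26)
    return _objects_from_labels(data, labels, n, spacing), labels


def filter_membrane(
    objects: Sequence[SegmentedObject],
    labels: np.ndarray,
    params: SegmentationParams,
    spacing: VoxelSpacing,
):
    """Discard membrane fragments below the volume threshold and keep the sheet.

    Objects below ``membrane_min_voxels`` (inclusive threshold: exactly-at
    survives) are discarded; if several survive, the largest is retained with
    a warning.  The winner is wrapped as a :class:`~qdepth.penetration.MembraneReference`
    with its apical surface extracted.  Raises
    :class:`MembraneNotFoundError` when nothing survives.
    """
    from .penetration import extract_apical_surface  # deferred: avoids module cycle

    surviving = [o for o in objects if o.voxel_count >= params.membrane_min_voxels]
    if not surviving:
        biggest = max((o.voxel_count for o in objects), default=0)
        raise MembraneNotFoundError(
            f"no membrane object ≥ {params.membrane_min_voxels} voxels "
            f"(largest candidate: {biggest} voxels)"
        )
    if len(surviving) > 1:
        warnings.warn(
            f"{len(surviving)} membrane candidates survive the volume filter; "
            "keeping the largest",
            stacklevel=2,
        )
    winner = max(surviving, key=lambda o: o.voxel_count)
    mask = labels == winner.object_id
    return extract_apical_surface(mask, spacing, obj=winner)


def filter_particles(
    objects: Sequence[SegmentedObject],
    threshold: float,
    intensity_max_global: float,
    params: SegmentationParams,
) -> list[SegmentedObject]:
    """Apply the two particle filters: volume and relative peak intensity.

    An object survives iff ``voxel_count >= qd_min_voxels`` (objects *below*
    the minimal volume of a single quantum dot are discarded) and its peak
    intensity reaches ``threshold + qd_rel_intensity_min * (intensity_max_global
    - threshold)``, i.e. 5 % of the threshold-to-maximum range by default.
    """
    if intensity_max_global < threshold:
        raise ValueError("global intensity maximum below threshold")
    cut = threshold + params.qd_rel_intensity_min * (intensity_max_global - threshold)
    return [
        o
        for o in objects
        if o.voxel_count >= params.qd_min_voxels and o.intensity_max >= cut
    ]


def watershed_split(
    stack: "VoxelStack | np.ndarray",
    mask: np.ndarray,
    sigma_um: float = 0.1,
    spacing: VoxelSpacing | None = None,
    min_distance_px: int = 7,
) -> tuple[list[SegmentedObject], np.ndarray]:
    """Split merged agglomerates by marker-based watershed.

    The intensity is smoothed with an anisotropic Gaussian of physical width
    ``sigma_um`` (converted per axis to voxels); seeds are the local maxima of
    the smoothed intensity inside the mask, at least ``min_distance_px``
    apart; flooding runs on the inverted smoothed intensity, restricted to the
    mask, so the output labels partition the mask exactly.  Components without
    a detected seed are seeded at their own intensity maximum, so the label
    count is never below the component count.  Markers are numbered in
    lexicographic voxel order, making the labelling deterministic.
    """
    data = _as_array(stack)
    if spacing is None:
        spacing = stack.spacing if isinstance(stack, VoxelStack) else VoxelSpacing()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty particle mask: nothing to split")

    sigma_vox = tuple(sigma_um / d for d in spacing.zyx)
    smoothed = ndi.gaussian_filter(data.astype(np.float64), sigma_vox, mode="reflect")

    comps, ncomp = ndi.label(mask, structure=STRUCT_26)
    peaks = peak_local_max(
        smoothed,
        min_distance=min_distance_px,
        labels=comps,
        exclude_border=False,
    )
    seeded = set(comps[tuple(peaks.T)]) if len(peaks) else set()
    extra = []
    for cid in range(1, ncomp + 1):
        if cid not in seeded:
            inside = np.where(comps == cid)
            best = np.argmax(smoothed[inside])
            extra.append([ax[best] for ax in inside])
    if extra:
        peaks = np.vstack([peaks, np.array(extra)]) if len(peaks) else np.array(extra)

    # deterministic marker numbering: lexicographic voxel order
    order = np.lexsort((peaks[:, 2], peaks[:, 1], peaks[:, 0]))
    peaks = peaks[order]
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)

    labels = watershed(-smoothed, markers, mask=mask, connectivity=3)
    objs = _objects_from_labels(data, labels, int(labels.max()), spacing)
    return objs, labels


def equivalent_diameter(obj: SegmentedObject, spacing: VoxelSpacing) -> float:
    """Diameter of the sphere with the object's physical volume:
    ``d = (6 V / π)^(1/3)`` with ``V = voxel_count · dx · dy · dz`` (µm)."""
    volume = obj.voxel_count * spacing.voxel_volume_um3
    return float((6.0 * volume / np.pi) ** (1.0 / 3.0))
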