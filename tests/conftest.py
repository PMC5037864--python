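import numpy as np
import pytest

from qdepth import (
    AgglomerateSpec,
    NoiseParams,
    PipelineConfig,
    PreprocessParams,
    SceneSpec,
    SegmentationParams,
    VoxelSpacing,
)

#: noise disabled entirely (pure forward model + background)
NO_NOISE = NoiseParams(poisson_scale=0.0, gaussian_sd=0.0, background=0.0)


@pytest.fixture
def spacing():
    return VoxelSpacing(0.06, 0.06, 0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def grid_cluster_scene(
    offset_um: float,
    shape=(40, 128, 128),
    n_clusters: int = 6,
    spots_per_cluster: int = 5,
    seed: int = 0,
    membrane_depth_um: float = 4.0,
    roughness_um: float = 0.0,
) -> SceneSpec:
    """Small test scene: agglomerates on a fixed lateral grid (no placement
    randomness), at one signed offset from the membrane."""
    spacing = VoxelSpacing()
    ey = (shape[1] - 1) * spacing.dy
    ex = (shape[2] - 1) * spacing.dx
    cols = int(np.ceil(np.sqrt(n_clusters)))
    rows = int(np.ceil(n_clusters / cols))
    ys = np.linspace(0.22 * ey, 0.78 * ey, rows)
    xs = np.linspace(0.22 * ex, 0.78 * ex, cols)
    centers = [(y, x) for y in ys for x in xs][:n_clusters]
    return SceneSpec(
        shape=shape,
        spacing=spacing,
        membrane_depth_um=membrane_depth_um,
        membrane_roughness_um=roughness_um,
        agglomerates=[
            AgglomerateSpec(
                n_spots=spots_per_cluster,
                offset_um=offset_um,
                y_um=y,
                x_um=x,
                lateral_jitter_um=0.3,
            )
            for y, x in centers
        ],
        seed=seed,
        geometry_seed=seed,
    )


def small_scene_config(**overrides) -> PipelineConfig:
    """Config scaled to the small test scenes: the membrane sheet of a
    128²-lateral stack is far below the production 10^5-voxel filter, and the
    agglomerates are segmented against a lower volume floor."""
    kw = dict(
        preprocess=PreprocessParams(deconvolve=False),
        segment=SegmentationParams(membrane_min_voxels=10_000, qd_min_voxels=100),
    )
    kw.update(overrides)
    return PipelineConfig(**kw)
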