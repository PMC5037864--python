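"""Synthetic confocal scenes of a labelled epithelial monolayer.

Every stage of the measurement pipeline is testable without microscopy data
because this module renders two- or three-channel z-stacks with *exact* ground
truth: a bright, roughly planar apical membrane sheet; sub-resolution particle
spots at known signed axial offsets from that sheet; agglomerates of several
spots; optional spherical organelles; Gaussian-PSF blur; and Poisson + Gaussian
noise.

Physical picture
----------------
Quantum dots (~13 nm) are far below the diffraction limit, so a spot is
rendered as the PSF itself — an anisotropic 3D Gaussian (axial width ≈ 3× the
lateral width, as in a high-NA confocal) — never as a solid.  At the exposure
concentrations modelled here the particles agglomerate, so the canonical
measurable object is a small cluster of emitters with sub-µm lateral scatter.
The membrane is a sheet of given thickness whose *upper* (apical, low-z)
boundary is the ground-truth reference surface; optional band-limited
undulation stands in for surface roughness such as microvilli.

Reproducibility contract
------------------------
``seed`` drives only the noise; ``geometry_seed`` drives the geometry
(roughness phases, agglomerate jitter).  Two specs that differ only in
``seed`` therefore produce identical noiseless renders, and an identical spec
renders bit-identically every time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np

from .stack_io import SceneGroundTruth, VoxelSpacing, VoxelStack

__all__ = [
    "SpotSpec",
    "AgglomerateSpec",
    "OrganelleSpec",
    "NoiseParams",
    "SceneSpec",
    "Scene",
    "render_scene",
    "render_agglomerate",
    "render_organelle_channel",
    "monolayer_scene",
]

# evaluate Gaussians out to this many sigmas (windowed rendering)
_TRUNC = 6.0


@dataclass(frozen=True)
class SpotSpec:
    """One point emitter: signed axial offset from the membrane surface (µm,
    negative = below the membrane, inside the cell), lateral position (µm)
    and peak amplitude (intensity units above background)."""

    offset_um: float
    y_um: float
    x_um: float
    amplitude: float = 300.0


@dataclass(frozen=True)
class AgglomerateSpec:
    """A cluster of ``n_spots`` emitters sharing one axial offset, laterally
    jittered within a disc of radius ``lateral_jitter_um`` around (y, x)."""

    n_spots: int
    offset_um: float
    y_um: float
    x_um: float
    amplitude: float = 300.0
    lateral_jitter_um: float = 0.3

    def __post_init__(self) -> None:
        if self.n_spots < 2:
            raise ValueError("an agglomerate needs at least 2 spots")
        if self.lateral_jitter_um < 0:
            raise ValueError("lateral jitter must be non-negative")


@dataclass(frozen=True)
class OrganelleSpec:
    """A spherical compartment (endosome/lysosome-like) of given diameter (µm),
    centred at (z, y, x) µm in stack coordinates."""

    diameter_um: float
    center_um: tuple[float, float, float]
    amplitude: float = 300.0


@dataclass(frozen=True)
class NoiseParams:
    """Detection-noise model: shot noise + additive Gaussian read noise.

    ``poisson_scale`` is the photon gain (counts per intensity unit); the
    rendered value is ``Poisson(signal·scale)/scale``, so larger scale means
    less relative shot noise and ``0`` disables shot noise entirely.
    ``background`` is a uniform offset added before the shot noise.  Defaults
    give SNR ≈ 10 at a default-amplitude spot peak.
    """

    poisson_scale: float = 0.35
    gaussian_sd: float = 3.0
    background: float = 20.0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_sd < 0 or self.background < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class SceneSpec:
    """Full description of one synthetic scene (YAML-serialisable)."""

    shape: tuple[int, int, int] = (64, 256, 256)
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)
    membrane_depth_um: float = 6.0
    membrane_thickness_um: float = 1.0
    membrane_roughness_um: float = 0.0
    membrane_amplitude: float = 400.0
    spots: list[SpotSpec] = field(default_factory=list)
    agglomerates: list[AgglomerateSpec] = field(default_factory=list)
    organelles: list[OrganelleSpec] = field(default_factory=list)
    psf_sigma_um: tuple[float, float] = (0.12, 0.35)  # (lateral, axial)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0
    geometry_seed: int = 0
    blur_membrane: bool = False

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3:
            raise ValueError("shape must be (nz, ny, nx)")
        if self.psf_sigma_um[0] <= 0 or self.psf_sigma_um[1] <= 0:
            raise ValueError("PSF sigmas must be positive")
        # membrane surface must stay clear of the z boundaries (3 voxels)
        dz = self.spacing.dz
        zmax = (self.shape[0] - 1) * dz
        margin = 3 * dz
        lo = self.membrane_depth_um - self.membrane_roughness_um
        hi = self.membrane_depth_um + self.membrane_roughness_um
        if lo < margin or hi > zmax - margin:
            raise ValueError(
                f"membrane surface ({lo:.2f}–{hi:.2f} µm) must stay ≥ 3 voxels "
                f"({margin:.2f} µm) from the z boundaries (stack depth {zmax:.2f} µm)"
            )

    @property
    def psf_sigma_vox(self) -> tuple[float, float, float]:
        """PSF sigma in voxels, array order (z, y, x)."""
        lat, ax = self.psf_sigma_um
        return (ax / self.spacing.dz, lat / self.spacing.dy, lat / self.spacing.dx)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple((n - 1) * d for n, d in zip(self.shape, self.spacing.zyx))

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if isinstance(v, np.integer):
                return int(v)
            if isinstance(v, np.floating):
                return float(v)
            return v

        d = plain(asdict(self))
        d["spacing"] = {"dx": self.spacing.dx, "dy": self.spacing.dy, "dz": self.spacing.dz}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scene keys: {sorted(unknown)}")
        if "spacing" in d and isinstance(d["spacing"], dict):
            d["spacing"] = VoxelSpacing(**d["spacing"])
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseParams(**d["noise"])
        if "spots" in d:
            d["spots"] = [s if isinstance(s, SpotSpec) else SpotSpec(**s) for s in d["spots"]]
        if "agglomerates" in d:
            d["agglomerates"] = [
                a if isinstance(a, AgglomerateSpec) else AgglomerateSpec(**a)
                for a in d["agglomerates"]
            ]
        if "organelles" in d:
            d["organelles"] = [
                o if isinstance(o, OrganelleSpec) else OrganelleSpec(**{
                    **o, "center_um": tuple(o["center_um"])
                })
                for o in d["organelles"]
            ]
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if "psf_sigma_um" in d:
            d["psf_sigma_um"] = tuple(d["psf_sigma_um"])
        return cls(**d)


class Scene(NamedTuple):
    membrane: VoxelStack
    particles: VoxelStack
    organelles: VoxelStack | None
    truth: SceneGroundTruth


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _surface_map(spec: SceneSpec) -> np.ndarray:
    """Apical surface height z(y, x) in µm: flat plane plus band-limited
    undulation (smooth sum of low-frequency sinusoids, geometry-seeded)."""
    _, ny, nx = spec.shape
    if spec.membrane_roughness_um <= 0:
        return np.full((ny, nx), spec.membrane_depth_um)
    rng = np.random.default_rng(np.random.SeedSequence([spec.geometry_seed, 7]))
    yy = np.arange(ny)[:, None] * spec.spacing.dy
    xx = np.arange(nx)[None, :] * spec.spacing.dx
    ly = ny * spec.spacing.dy
    lx = nx * spec.spacing.dx
    surf = np.zeros((ny, nx))
    # a handful of low-order modes: wavelengths >= 1/4 of the field
    for _ in range(6):
        ky = rng.integers(0, 5) * 2 * np.pi / ly
        kx = rng.integers(0, 5) * 2 * np.pi / lx
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.3, 1.0)
        surf += amp * np.sin(ky * yy + kx * xx + phase)
    peak = np.abs(surf).max()
    if peak > 0:
        surf *= spec.membrane_roughness_um / peak
    return spec.membrane_depth_um + surf


def _expand_spots(spec: SceneSpec) -> tuple[list[SpotSpec], dict[int, int]]:
    """Explicit spots plus agglomerate members, with membership indices.

    Agglomerate jitter is drawn from ``geometry_seed`` so the noiseless render
    is independent of the noise seed.
    """
    spots = list(spec.spots)
    membership: dict[int, int] = {}
    rng = np.random.default_rng(np.random.SeedSequence([spec.geometry_seed, 13]))
    for agg_id, agg in enumerate(spec.agglomerates):
        for _ in range(agg.n_spots):
            # uniform in a disc of radius lateral_jitter_um
            r = agg.lateral_jitter_um * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            idx = len(spots)
            spots.append(
                SpotSpec(
                    offset_um=agg.offset_um,
                    y_um=agg.y_um + r * math.sin(th),
                    x_um=agg.x_um + r * math.cos(th),
                    amplitude=agg.amplitude,
                )
            )
            membership[idx] = agg_id
    return spots, membership


# ---------------------------------------------------------------------------
# noiseless forward models
# ---------------------------------------------------------------------------

def _add_gaussian_spot(
    canvas: np.ndarray,
    center_vox: tuple[float, float, float],
    sigma_vox: tuple[float, float, float],
    amplitude: float,
) -> None:
    """Accumulate one PSF-shaped emitter, evaluated analytically at voxel
    centres within a ±6σ window (exact separable forward model)."""
    nz, ny, nx = canvas.shape
    axes = []
    for c, s, n in zip(center_vox, sigma_vox, (nz, ny, nx)):
        lo = max(0, int(math.floor(c - _TRUNC * s)))
        hi = min(n, int(math.ceil(c + _TRUNC * s)) + 1)
        idx = np.arange(lo, hi)
        axes.append((idx, np.exp(-((idx - c) ** 2) / (2 * s * s))))
    (zz, gz), (yy, gy), (xx, gx) = axes
    if len(zz) == 0 or len(yy) == 0 or len(xx) == 0:
        return
    canvas[np.ix_(zz, yy, xx)] += amplitude * (
        gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    )


def _membrane_model(spec: SceneSpec, surface: np.ndarray) -> np.ndarray:
    """Sheet of stated thickness below the surface map, with sub-voxel
    (anti-aliased) axial coverage so the upper boundary is exactly the truth."""
    nz = spec.shape[0]
    dz = spec.spacing.dz
    z_lo = np.arange(nz)[:, None, None] * dz - dz / 2
    z_hi = z_lo + dz
    top = surface[None, :, :]
    bot = top + spec.membrane_thickness_um
    cover = (np.minimum(z_hi, bot) - np.maximum(z_lo, top)).clip(0, None) / dz
    model = (spec.membrane_amplitude * cover).astype(np.float32)
    if spec.blur_membrane:
        from scipy.ndimage import gaussian_filter

        model = gaussian_filter(model, spec.psf_sigma_vox, mode="reflect")
    return model


def _particle_model(
    spec: SceneSpec, spots: Sequence[SpotSpec], surface: np.ndarray
) -> tuple[np.ndarray, list[tuple[float, float, float]]]:
    canvas = np.zeros(spec.shape, np.float32)
    sig = spec.psf_sigma_vox
    dz, dy, dx = spec.spacing.zyx
    ez, ey, ex = spec.extent_um
    positions = []
    for i, spot in enumerate(spots):
        iy = min(max(int(round(spot.y_um / dy)), 0), spec.shape[1] - 1)
        ix = min(max(int(round(spot.x_um / dx)), 0), spec.shape[2] - 1)
        z_um = float(surface[iy, ix]) - spot.offset_um
        if not (0 <= z_um <= ez and 0 <= spot.y_um <= ey and 0 <= spot.x_um <= ex):
            raise ValueError(
                f"spot {i} at (z={z_um:.2f}, y={spot.y_um:.2f}, x={spot.x_um:.2f}) µm "
                f"lies outside the stack extent ({ez:.2f}, {ey:.2f}, {ex:.2f}) µm"
            )
        _add_gaussian_spot(
            canvas, (z_um / dz, spot.y_um / dy, spot.x_um / dx), sig, spot.amplitude
        )
        positions.append((z_um, spot.y_um, spot.x_um))
    return canvas, positions


def _organelle_model(spec: SceneSpec) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    dz, dy, dx = spec.spacing.zyx
    for i, org in enumerate(spec.organelles):
        if org.diameter_um < 2 * dx:
            raise ValueError(
                f"organelle {i}: diameter {org.diameter_um} µm below 2 lateral voxels "
                f"({2 * dx} µm) is unresolvable"
            )
    canvas = np.zeros(spec.shape, np.float32)
    zz = np.arange(spec.shape[0])[:, None, None] * dz
    yy = np.arange(spec.shape[1])[None, :, None] * dy
    xx = np.arange(spec.shape[2])[None, None, :] * dx
    for org in spec.organelles:
        cz, cy, cx = org.center_um
        dist = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
        # filled sphere with a one-lateral-voxel anti-aliased rim
        cover = np.clip((org.diameter_um / 2 - dist) / dx + 0.5, 0, 1)
        canvas += org.amplitude * cover.astype(np.float32)
    return gaussian_filter(canvas, spec.psf_sigma_vox, mode="reflect")


def _apply_noise(model: np.ndarray, noise: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    out = model.astype(np.float32) + np.float32(noise.background)
    if noise.poisson_scale > 0:
        out = (rng.poisson(out * noise.poisson_scale) / noise.poisson_scale).astype(np.float32)
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, out.shape).astype(np.float32)
    return np.clip(out, 0, None)


# ---------------------------------------------------------------------------
# public renderers
# ---------------------------------------------------------------------------

def render_scene(spec: SceneSpec) -> Scene:
    """Render membrane + particle (+ optional organelle) channels with truth.

    Noise is applied after blur, per channel, from independent streams spawned
    off ``spec.seed``; identical spec + seed renders bit-identically.
    """
    surface = _surface_map(spec)
    spots, membership = _expand_spots(spec)

    mem_model = _membrane_model(spec, surface)
    par_model, positions = _particle_model(spec, spots, surface)
    org_model = _organelle_model(spec) if spec.organelles else None

    streams = np.random.SeedSequence([int(spec.seed), 101]).spawn(3)
    membrane = VoxelStack(
        _apply_noise(mem_model, spec.noise, np.random.default_rng(streams[0])),
        spec.spacing,
        channel_name="membrane",
    )
    particles = VoxelStack(
        _apply_noise(par_model, spec.noise, np.random.default_rng(streams[1])),
        spec.spacing,
        channel_name="particles",
    )
    organelles = None
    if org_model is not None:
        organelles = VoxelStack(
            _apply_noise(org_model, spec.noise, np.random.default_rng(streams[2])),
            spec.spacing,
            channel_name="organelles",
        )

    truth = SceneGroundTruth(
        membrane_plane_z=float(spec.membrane_depth_um),
        spot_true_offsets=[s.offset_um for s in spots],
        spot_positions=positions,
        agglomerate_membership=membership,
        surface_map_um=surface,
        organelle_diameters=[o.diameter_um for o in spec.organelles],
    )
    truth.validate_consistency(spec.spacing)
    return Scene(membrane, particles, organelles, truth)


def render_agglomerate(spec: SceneSpec, cluster: AgglomerateSpec) -> VoxelStack:
    """Noiseless particle-channel contribution of a single agglomerate.

    Member placement uses the same geometry stream as :func:`render_scene`
    would for a spec whose only agglomerate is ``cluster``.
    """
    probe = SceneSpec(
        shape=spec.shape,
        spacing=spec.spacing,
        membrane_depth_um=spec.membrane_depth_um,
        membrane_thickness_um=spec.membrane_thickness_um,
        membrane_roughness_um=spec.membrane_roughness_um,
        agglomerates=[cluster],
        psf_sigma_um=spec.psf_sigma_um,
        geometry_seed=spec.geometry_seed,
    )
    surface = _surface_map(probe)
    spots, _ = _expand_spots(probe)
    model, _ = _particle_model(probe, spots, surface)
    return VoxelStack(model, spec.spacing, channel_name="particles")


def render_organelle_channel(spec: SceneSpec) -> VoxelStack:
    """Noiseless organelle channel (PSF-blurred spheres of stated diameters)."""
    if not spec.organelles:
        raise ValueError("spec.organelles is empty: nothing to render")
    return VoxelStack(_organelle_model(spec), spec.spacing, channel_name="organelles")


def monolayer_scene(
    offset_um: float,
    shape: tuple[int, int, int] = (128, 256, 256),
    n_clusters: int = 4,
    spots_per_cluster: int = 5,
    membrane_depth_um: float = 6.0,
    roughness_um: float = 0.0,
    amplitude: float = 300.0,
    jitter_um: float = 0.3,
    spacing: VoxelSpacing | None = None,
    seed: int = 0,
    geometry_seed: int = 0,
) -> SceneSpec:
    """Canonical exposure scene: a monolayer with particle agglomerates at one
    signed axial offset from the apical membrane.

    At the exposure concentrations modelled here, particles agglomerate; the
    measurable object is a cluster of ``spots_per_cluster`` emitters scattered
    within a ``jitter_um`` disc.  Cluster centres are placed by the geometry
    stream with a margin from the lateral borders and a minimum mutual
    separation so clusters segment as distinct objects.
    """
    spacing = spacing or VoxelSpacing()
    rng = np.random.default_rng(np.random.SeedSequence([int(geometry_seed), 29]))
    ey = (shape[1] - 1) * spacing.dy
    ex = (shape[2] - 1) * spacing.dx
    extent = min(ey, ex)
    margin = min(1.8, 0.15 * extent)
    min_sep = min(2.5, 0.28 * extent)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_clusters:
        attempts += 1
        if attempts > 10_000:
            raise ValueError(
                f"cannot place {n_clusters} clusters {min_sep:.2f} µm apart in "
                f"{ey:.1f}×{ex:.1f} µm"
            )
        if attempts % 2000 == 0:
            centers.clear()  # restart a stuck greedy placement
        y = rng.uniform(margin, ey - margin)
        x = rng.uniform(margin, ex - margin)
        if all(math.hypot(y - cy, x - cx) >= min_sep for cy, cx in centers):
            centers.append((y, x))
    return SceneSpec(
        shape=shape,
        spacing=spacing,
        membrane_depth_um=membrane_depth_um,
        membrane_roughness_um=roughness_um,
        agglomerates=[
            AgglomerateSpec(
                n_spots=spots_per_cluster,
                offset_um=offset_um,
                y_um=cy,
                x_um=cx,
                amplitude=amplitude,
                lateral_jitter_um=jitter_um,
            )
            for cy, cx in centers
        ],
        seed=seed,
        geometry_seed=geometry_seed,
    )
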