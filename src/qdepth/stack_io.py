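"""Image-stack and result-table I/O with physical-unit bookkeeping.

All stacks are single-channel 3D intensity grids indexed ``(z, y, x)`` with
anisotropic voxel spacing in micrometres.  The axis convention is fixed here,
once, for the whole package: **z increases from the apical (lumen-facing) side
of the monolayer toward the basal side**, so a particle *below* the apical
membrane — inside the cell — sits at larger z than the membrane surface, and
its signed axial distance to that surface is negative.  Every downstream
module inherits this convention through :class:`VoxelStack` and never
re-decides it.

Files are plain TIFF / OME-TIFF; voxel spacing travels in OME ``PhysicalSize*``
attributes (or ImageJ-style metadata on read).  Result tables are CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AXIS_CONVENTION",
    "VoxelSpacing",
    "VoxelStack",
    "SceneGroundTruth",
    "SpacingError",
    "read_stack",
    "write_stack",
    "write_records",
    "read_records",
]

#: Fixed axis convention for the whole package (see module docstring).
AXIS_CONVENTION = "z-apical-to-basal"

#: Minimum analyzable stack: fewer planes/pixels than this cannot carry a
#: membrane sheet plus particles at measurable offsets.
MIN_SHAPE = (8, 32, 32)

RECORD_COLUMNS = ["stack_id", "object_id", "axial_distance_um", "volume_voxels", "com_z_um"]


class SpacingError(ValueError):
    """Raised when voxel spacing is missing, non-physical, or laterally anisotropic."""


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel spacing in µm/voxel.

    The pipeline assumes isotropic lateral sampling (``dx == dy``); the axial
    step ``dz`` is typically coarser.  Defaults are 60 nm laterally and 0.2 µm
    axially (a typical confocal section spacing at NA 1.4 — fine enough to
    resolve sub-micrometre penetration depths).
    """

    dx: float = 0.06
    dy: float = 0.06
    dz: float = 0.2

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise SpacingError(f"spacing {name}={v!r} must be a finite positive length")
        if not math.isclose(self.dx, self.dy, rel_tol=1e-9):
            raise SpacingError(
                f"lateral spacing must be isotropic, got dx={self.dx} µm, dy={self.dy} µm"
            )

    @property
    def zyx(self) -> tuple[float, float, float]:
        """Spacing in array-axis order ``(dz, dy, dx)``."""
        return (self.dz, self.dy, self.dx)

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz


@dataclass
class VoxelStack:
    """A single-channel 3D intensity grid with physical spacing.

    ``data`` is indexed ``(z, y, x)`` with z the slowest axis, intensities
    finite and non-negative.
    """

    data: np.ndarray
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)
    channel_name: str = ""
    axis_convention: str = AXIS_CONVENTION

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got shape {self.data.shape}")
        if any(s < m for s, m in zip(self.data.shape, MIN_SHAPE)):
            raise ValueError(
                f"stack shape {self.data.shape} below minimum analyzable {MIN_SHAPE}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("stack intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("stack intensities must be non-negative")
        if self.axis_convention != AXIS_CONVENTION:
            raise ValueError(f"unsupported axis convention {self.axis_convention!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "VoxelStack":
        """Same spacing/labels, new voxel data."""
        return replace(self, data=data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelStack):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and self.spacing == other.spacing
            and self.channel_name == other.channel_name
        )


@dataclass
class SceneGroundTruth:
    """Exact geometry behind a synthetic scene.

    Offsets are signed axial distances from the apical membrane surface in µm,
    negative below the membrane (inside the cell) — the same convention as the
    measured penetration depths, so a recovered peak position can be compared
    to ``spot_true_offsets`` directly.
    """

    membrane_plane_z: float
    spot_true_offsets: list[float] = field(default_factory=list)
    spot_positions: list[tuple[float, float, float]] = field(default_factory=list)
    agglomerate_membership: dict[int, int] = field(default_factory=dict)
    surface_map_um: np.ndarray | None = None
    organelle_diameters: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.spot_true_offsets) != len(self.spot_positions):
            raise ValueError("one true offset per spot position is required")

    def validate_consistency(self, spacing: VoxelSpacing) -> None:
        """Check offsets, positions and the membrane surface agree to one axial voxel."""
        for i, (off, pos) in enumerate(zip(self.spot_true_offsets, self.spot_positions)):
            if self.surface_map_um is not None:
                iy = int(round(pos[1] / spacing.dy))
                ix = int(round(pos[2] / spacing.dx))
                iy = min(max(iy, 0), self.surface_map_um.shape[0] - 1)
                ix = min(max(ix, 0), self.surface_map_um.shape[1] - 1)
                surf = float(self.surface_map_um[iy, ix])
            else:
                surf = self.membrane_plane_z
            if abs((surf - pos[0]) - off) > spacing.dz:
                raise ValueError(
                    f"spot {i}: offset {off} µm inconsistent with position z={pos[0]} µm "
                    f"and surface z={surf} µm"
                )


def _as_array(stack: "VoxelStack | np.ndarray") -> np.ndarray:
    """Accept either a VoxelStack or a bare array (used by small-grid oracles)."""
    return stack.data if isinstance(stack, VoxelStack) else np.asarray(stack)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def write_stack(
    stack: "VoxelStack | Sequence[VoxelStack]",
    path: str | Path,
) -> Path:
    """Write one or several channels to a TIFF with spacing metadata.

    A single :class:`VoxelStack` is written as ZYX; a sequence of stacks
    (sharing shape and spacing) as a ZCYX hyperstack.  Spacing travels in
    ImageJ-style metadata (lateral in the TIFF resolution tags, axial in
    ``spacing``), which keeps the file byte-deterministic.
    ``read_stack(write_stack(s)) == s`` bit-exactly for integer data.
    """
    path = Path(path)
    stacks = [stack] if isinstance(stack, VoxelStack) else list(stack)
    if not stacks:
        raise ValueError("no channels to write")
    sp = stacks[0].spacing
    for s in stacks[1:]:
        if s.spacing != sp or s.shape != stacks[0].shape:
            raise ValueError("all channels must share shape and spacing")
    if len(stacks) == 1:
        data = stacks[0].data
        axes = "ZYX"
    else:
        data = np.stack([s.data for s in stacks], axis=1)  # Z, C, Y, X
        axes = "ZCYX"
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / sp.dx, 1.0 / sp.dy),
        metadata={"spacing": sp.dz, "unit": "um", "axes": axes},
    )
    return path


_UNIT_TO_UM = {
    "µm": 1.0, "um": 1.0, "micron": 1.0, "µm.": 1.0,
    "nm": 1e-3, "mm": 1e3, "m": 1e6, "µm": 1.0,
}


def _spacing_from_ome(tif: tifffile.TiffFile) -> VoxelSpacing | None:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = root.tag.split("}")[0] + "}" if "}" in root.tag else ""
        px = root.find(f".//{ns}Pixels")
        if px is None:
            return None
        vals = {}
        for ax in ("X", "Y", "Z"):
            raw = px.get(f"PhysicalSize{ax}")
            if raw is None:
                return None
            unit = px.get(f"PhysicalSize{ax}Unit", "µm")
            vals[ax] = float(raw) * _UNIT_TO_UM.get(unit, 1.0)
        return VoxelSpacing(dx=vals["X"], dy=vals["Y"], dz=vals["Z"])
    except (SpacingError, ValueError):
        raise
    except Exception:
        return None


def _spacing_from_imagej(tif: tifffile.TiffFile) -> VoxelSpacing | None:
    try:
        meta = tif.imagej_metadata or {}
        dz = meta.get("spacing")
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if dz is None or xres is None or yres is None:
            return None
        scale = _UNIT_TO_UM.get(meta.get("unit", "µm"), 1.0)
        # resolution tags are rationals; round away their quantisation error
        dx = round(xres.value[1] / xres.value[0] * scale, 9)
        dy = round(yres.value[1] / yres.value[0] * scale, 9)
        return VoxelSpacing(dx=dx, dy=dy, dz=float(dz) * scale)
    except (SpacingError, ValueError):
        raise
    except Exception:
        return None


def read_stack(
    path: str | Path,
    channel: int = 0,
    spacing: VoxelSpacing | None = None,
    axes: str | None = None,
    channel_name: str = "",
) -> VoxelStack:
    """Read one channel of a TIFF/OME-TIFF into a :class:`VoxelStack`.

    Parameters
    ----------
    channel
        Channel index for multi-channel files (CZYX or ZCYX, auto-detected
        from metadata; ``axes`` overrides the detection).
    spacing
        Explicit spacing override.  Without it the file metadata must carry
        voxel spacing — a missing spacing is a hard error, never silently
        assumed, because every reported distance is in µm.
    axes
        Axis-layout override, e.g. ``"CZYX"`` or ``"ZCYX"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = axes or series.axes.upper()
        meta_spacing = _spacing_from_ome(tif) if tif.ome_metadata else None
        if meta_spacing is None:
            meta_spacing = _spacing_from_imagej(tif)

    if spacing is None:
        spacing = meta_spacing
    if spacing is None:
        raise SpacingError(
            f"{path}: no voxel spacing in metadata and none supplied; distances would be "
            "unit-unsafe. Pass spacing= (or configure spacing:) explicitly."
        )

    if data.ndim == 3:
        if channel != 0:
            raise IndexError(f"{path} is single-channel; channel={channel} out of range")
        vol = data
    elif data.ndim == 4:
        file_axes = (file_axes or "CZYX")[:4]
        if file_axes == "CZYX":
            c_axis = 0
        elif file_axes == "ZCYX":
            c_axis = 1
        else:
            # fall back: the smaller of the two leading axes is the channel axis
            c_axis = 0 if data.shape[0] <= data.shape[1] else 1
        if channel >= data.shape[c_axis]:
            raise IndexError(
                f"{path}: channel {channel} out of range ({data.shape[c_axis]} channels)"
            )
        vol = np.take(data, channel, axis=c_axis)
    else:
        raise ValueError(f"{path}: expected a 3D or 4D stack, got shape {data.shape}")

    return VoxelStack(data=vol, spacing=spacing, channel_name=channel_name)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_records(records: Sequence, path: str | Path) -> Path:
    """Write penetration records as a CSV table (header-only when empty).

    Columns: ``stack_id, object_id, axial_distance_um, volume_voxels, com_z_um``.
    Distances round-trip at full float precision.
    """
    path = Path(path)
    rows = [
        {
            "stack_id": r.stack_id,
            "object_id": r.object_id,
            "axial_distance_um": repr(float(r.axial_distance_um)),
            "volume_voxels": r.volume_voxels,
            "com_z_um": repr(float(r.com[0])),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_records(path: str | Path) -> pd.DataFrame:
    """Load a penetration-record table written by :func:`write_records`."""
    df = pd.read_csv(path, dtype={"stack_id": str}, float_precision="round_trip")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing record columns {sorted(missing)}")
    return df
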