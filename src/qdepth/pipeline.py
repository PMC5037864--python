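"""End-to-end orchestration: simulate → preprocess → segment → analyze.

One :class:`PipelineConfig` governs everything; no hidden defaults outside it.
Every run writes its resolved configuration next to its outputs, so a result
can always be traced to the exact parameters that produced it, and re-running
with the same configuration and inputs reproduces every output byte for byte
(timestamps live only in the log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import scenes
from .penetration import (
    DepthFitResult,
    PenetrationRecord,
    classify_penetration,
    measure_distance,
    pool_and_fit,
)
from .preprocess import PreprocessParams, preprocess_membrane, preprocess_particles
from .segment import (
    SegmentationParams,
    filter_membrane,
    filter_particles,
    label_objects,
    otsu_threshold,
    watershed_split,
)
from .stack_io import VoxelSpacing, VoxelStack, read_stack, write_records, write_stack

__all__ = [
    "PenetrationParams",
    "PipelineConfig",
    "PipelineError",
    "PipelineReport",
    "analyze_pair",
    "run_pipeline",
    "make_fixture_suite",
]

log = logging.getLogger("qdepth")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stack id and stage name."""


@dataclass(frozen=True)
class PenetrationParams:
    bin_width_um: float = 0.2
    se_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.bin_width_um <= 0:
            raise ValueError("bin width must be positive")
        if self.se_factor < 0:
            raise ValueError("se_factor must be >= 0")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    spacing: VoxelSpacing | None = None  # None: trust file metadata
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segment: SegmentationParams = field(default_factory=SegmentationParams)
    penetration: PenetrationParams = field(default_factory=PenetrationParams)
    membrane_channel: int = 0
    particle_channel: int = 1
    seed: int = 0
    output_dir: str = "qdepth-out"

    def to_dict(self) -> dict:
        d: dict = {
            "membrane_channel": self.membrane_channel,
            "particle_channel": self.particle_channel,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "preprocess": dataclasses.asdict(self.preprocess),
            "segment": dataclasses.asdict(self.segment),
            "penetration": dataclasses.asdict(self.penetration),
        }
        d["spacing"] = (
            None
            if self.spacing is None
            else {"dx": self.spacing.dx, "dy": self.spacing.dy, "dz": self.spacing.dz}
        )
        d["preprocess"]["psf_sigma_um"] = list(self.preprocess.psf_sigma_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def sub(key, klass):
            if key in d and isinstance(d[key], dict):
                extra = set(d[key]) - {f.name for f in dataclasses.fields(klass)}
                if extra:
                    raise ValueError(f"unknown config keys under {key}: {sorted(extra)}")
                kw = dict(d[key])
                if "psf_sigma_um" in kw:
                    kw["psf_sigma_um"] = tuple(kw["psf_sigma_um"])
                d[key] = klass(**kw)

        if d.get("spacing") is not None and isinstance(d["spacing"], dict):
            d["spacing"] = VoxelSpacing(**d["spacing"])
        sub("preprocess", PreprocessParams)
        sub("segment", SegmentationParams)
        sub("penetration", PenetrationParams)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class PipelineReport:
    records: list[PenetrationRecord]
    fit: DepthFitResult | None
    verdict: str | None
    stack_tables: dict[str, pd.DataFrame]
    membrane_otsu: dict[str, float]
    particle_otsu: dict[str, float]


def analyze_pair(
    membrane: VoxelStack,
    particles: VoxelStack,
    config: PipelineConfig,
    stack_id: str = "stack",
) -> tuple[list[PenetrationRecord], pd.DataFrame, dict]:
    """Run preprocessing, segmentation and distance measurement on one stack.

    Returns the penetration records, a per-object table, and a dict of
    intermediate quantities (thresholds, membrane reference) for reporting.
    """
    stage = "preprocess"
    try:
        mem_proc = preprocess_membrane(membrane, config.preprocess)
        par_proc = preprocess_particles(particles, config.preprocess)

        stage = "segment-membrane"
        mem_thr = otsu_threshold(mem_proc)
        mem_objects, mem_labels = label_objects(mem_proc, mem_thr)
        membrane_ref = filter_membrane(
            mem_objects, mem_labels, config.segment, membrane.spacing
        )

        stage = "segment-particles"
        par_thr = otsu_threshold(par_proc)
        mask = par_proc.data > par_thr
        records: list[PenetrationRecord] = []
        kept = []
        if mask.any():
            objects, _ = watershed_split(
                par_proc,
                mask,
                config.segment.watershed_sigma_um,
                particles.spacing,
                config.segment.seed_min_distance_px,
            )
            kept = filter_particles(
                objects, par_thr, float(par_proc.data.max()), config.segment
            )
            stage = "measure"
            records = [measure_distance(o, membrane_ref, stack_id) for o in kept]
    except Exception as exc:  # annotate with provenance, re-raise
        raise PipelineError(f"stack {stack_id!r}, stage {stage}: {exc}") from exc

    table = pd.DataFrame(
        {
            "stack_id": stack_id,
            "object_id": [o.object_id for o in kept],
            "voxel_count": [o.voxel_count for o in kept],
            "com_z_um": [o.com_um[0] for o in kept],
            "com_y_um": [o.com_um[1] for o in kept],
            "com_x_um": [o.com_um[2] for o in kept],
            "intensity_max": [o.intensity_max for o in kept],
            "axial_distance_um": [r.axial_distance_um for r in records],
        }
    )
    info = {"membrane_otsu": mem_thr, "particle_otsu": par_thr, "membrane": membrane_ref}
    return records, table, info


def _plot_fit(fit: DepthFitResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers, counts = fit.histogram
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(centers, counts, width=fit.bin_width_um * 0.95, color="0.7", label="distances")
    if fit.fit_ok:
        xs = np.linspace(centers.min(), centers.max(), 400)
        ax.plot(
            xs,
            fit.amplitude * np.exp(-((xs - fit.x_c) ** 2) / (2 * fit.sigma_fit**2)),
            "r-",
            label=f"Gauss fit: $x_c$={fit.x_c:.2f} µm",
        )
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("axial distance to apical membrane (µm)")
    ax.set_ylabel("objects")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(
    config: PipelineConfig,
    inputs: Sequence[str | Path],
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Analyze a list of two-channel stacks and pool the penetration depths.

    Writes, under ``out_dir`` (default ``config.output_dir``): per-object
    tables, the pooled record table, histogram CSV, fit JSON, a histogram
    plot, and the resolved configuration.
    """
    if not inputs:
        raise ValueError("no input stacks given")
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    all_records: list[PenetrationRecord] = []
    tables = []
    mem_thr: dict[str, float] = {}
    par_thr: dict[str, float] = {}
    for path in inputs:
        path = Path(path)
        stack_id = path.stem
        membrane = read_stack(
            path, config.membrane_channel, spacing=config.spacing, channel_name="membrane"
        )
        particles = read_stack(
            path, config.particle_channel, spacing=config.spacing, channel_name="particles"
        )
        records, table, info = analyze_pair(membrane, particles, config, stack_id)
        log.info(
            "stack %s: membrane otsu %.3f, particle otsu %.3f, %d objects kept",
            stack_id,
            info["membrane_otsu"],
            info["particle_otsu"],
            len(records),
        )
        all_records.extend(records)
        tables.append(table)
        mem_thr[stack_id] = info["membrane_otsu"]
        par_thr[stack_id] = info["particle_otsu"]

    objects_table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    objects_table.to_csv(out / "objects.csv", index=False)
    write_records(all_records, out / "records.csv")

    fit = None
    verdict = None
    if len(all_records) >= 20:
        fit = pool_and_fit(
            all_records,
            config.penetration.bin_width_um,
            n_stacks=len(inputs),
        )
        if fit.fit_ok:
            verdict = classify_penetration(fit, config.penetration.se_factor)
        pd.DataFrame(
            {"bin_center_um": fit.histogram[0], "count": fit.histogram[1]}
        ).to_csv(out / "histogram.csv", index=False)
        _plot_fit(fit, out / "depth_histogram.png")

    report = {
        "n_stacks": len(inputs),
        "n_objects": len(all_records),
        "membrane_otsu": mem_thr,
        "particle_otsu": par_thr,
        "fit": None
        if fit is None
        else {
            "x_c_um": fit.x_c,
            "x_c_se_um": fit.x_c_se,
            "sigma_um": fit.sigma_fit,
            "sigma_se_um": fit.sigma_se,
            "fit_ok": fit.fit_ok,
            "degenerate": fit.degenerate,
            "shapiro_p": fit.shapiro_p,
            "mean_ml_um": fit.mean_ml,
            "sd_ml_um": fit.sd_ml,
            "bin_width_um": fit.bin_width_um,
        },
        "verdict": verdict,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return PipelineReport(
        records=all_records,
        fit=fit,
        verdict=verdict,
        stack_tables={t["stack_id"].iloc[0]: t for t in tables if len(t)},
        membrane_otsu=mem_thr,
        particle_otsu=par_thr,
    )


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

#: the two depth regimes of interest: penetrated vs membrane-associated
FIXTURE_OFFSETS_UM = (-1.3, 0.0)


def make_fixture_suite(
    seed: int,
    out: str | Path,
    shape: tuple[int, int, int] = (48, 256, 256),
) -> list[Path]:
    """Write the four canonical scenes (flat/rough × deep/surface particles).

    Each scene directory holds a two-channel OME-TIFF plus the ground truth
    as CSV and JSON.  Byte-identical for identical seeds.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for offset in FIXTURE_OFFSETS_UM:
        for rough in (False, True):
            name = f"{'rough' if rough else 'flat'}_{'deep' if offset < 0 else 'surface'}"
            sdir = out / name
            sdir.mkdir(exist_ok=True)
            spec = scenes.monolayer_scene(
                offset_um=offset,
                shape=shape,
                roughness_um=0.4 if rough else 0.0,
                seed=seed,
                geometry_seed=seed + (1 if rough else 0) + (2 if offset < 0 else 0),
            )
            scene = scenes.render_scene(spec)
            write_stack([scene.membrane, scene.particles], sdir / "stack.tif")
            truth = scene.truth
            pd.DataFrame(
                {
                    "spot": range(len(truth.spot_true_offsets)),
                    "true_offset_um": truth.spot_true_offsets,
                    "z_um": [p[0] for p in truth.spot_positions],
                    "y_um": [p[1] for p in truth.spot_positions],
                    "x_um": [p[2] for p in truth.spot_positions],
                    "agglomerate": [
                        truth.agglomerate_membership.get(i, -1)
                        for i in range(len(truth.spot_true_offsets))
                    ],
                }
            ).to_csv(sdir / "truth.csv", index=False)
            (sdir / "truth.json").write_text(
                json.dumps(
                    {
                        "membrane_plane_z_um": truth.membrane_plane_z,
                        "offsets_um": truth.spot_true_offsets,
                        "n_spots": len(truth.spot_true_offsets),
                        "roughness_um": spec.membrane_roughness_um,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            written.append(sdir)
    return written
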