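"""End-to-end pipeline: preprocess -> segment -> morphometry -> quantify.

Driven by a flat :class:`PipelineConfig` (loadable from YAML; unknown keys
are rejected so typos fail loudly). Every stage writes its intermediate
artifacts and the run ends with a manifest recording package version,
parameters and seeds, so every number in the report is reproducible from
the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io, morphometry, preprocess, quantify, segment
from .types import DepositionReport, RegionLabelMap, VolumeImage

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with defaults; flags override YAML values.

    The wall grey range (``grow_lo``/``grow_hi``) is quoted on the *raw*
    8-bit scale. The pipeline runs invert -> bilateral -> region grow; the
    grow range is conjugated to [255-hi, 255-lo] on the inverted volume,
    which is equivalent because both inversion and the bilateral filter
    commute with the intensity flip.
    """

    # inputs
    structure_path: str | None = None
    fluorescence_path: str | None = None
    labels_path: str | None = None
    tiles_dir: str | None = None
    positions_csv: str | None = None
    voxel_size: tuple[float, float, float] | None = None
    out_dir: str = "pulmovox_run"
    # preprocess
    search_radius: int = 3
    illumination: bool = True
    smoothing_scale: float | None = None
    defect_z: float = 3.5
    # segment
    invert_first: bool = True
    bilateral_kernel: int = 11
    sigma_range: float = 30.0
    grow_lo: int = 110
    grow_hi: int = 255
    grow_connectivity: int = 6
    seed_voxel: tuple[int, int, int] | None = None
    # morphometry
    run_morphometry: bool = True
    prune_length: float = 10.0
    fit_length: float = 50.0
    root_hint_um: tuple[float, float, float] | None = None
    # quantify
    detect_threshold: float = 50.0
    detect_min_voxels: int = 4
    single_particle_volume: float | None = None
    surface_distance: float = 10.0
    density_scale: float = 1.0
    seed: int = 0

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> DepositionReport | None:
    """Execute the full analysis chain and write all artifacts.

    Stages (any may be skipped if its inputs are absent): tile stitching
    + illumination correction + defect removal; inversion + bilateral
    filtering + seeded region growing; skeletonization + generations +
    bifurcation angles; particle detection + region assignment +
    deposition statistics. Returns the deposition report, or ``None`` in
    a structure-only run (no fluorescence channel).
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": cfg.to_dict(), "stages": []}

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        log.info("stage %s: %s", stage, info)

    try:
        # ---- preprocess -------------------------------------------------
        if cfg.tiles_dir is not None:
            tiles = io.read_tiles(cfg.tiles_dir, cfg.positions_csv)
            res = preprocess.stitch_tiles(tiles, search_radius=cfg.search_radius)
            structure = res.volume
            record("stitch", n_tiles=len(tiles.tiles), fallback=res.fallback_tiles)
            if cfg.illumination:
                structure = preprocess.correct_illumination(structure, cfg.smoothing_scale)
                record("illumination", smoothing_scale=cfg.smoothing_scale)
            structure, defects = preprocess.remove_defects(structure, cfg.defect_z)
            record("defects", n_lines=len(defects))
            io.write_volume(structure, out / "stitched.tif")
        elif cfg.structure_path is not None:
            structure = io.read_volume(cfg.structure_path, voxel_size=cfg.voxel_size)
        else:
            raise ValueError("config must give either tiles_dir or structure_path")
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", e) from e

    # ---- segment --------------------------------------------------------
    airway = None
    if cfg.seed_voxel is not None:
        try:
            work = structure
            lo, hi = cfg.grow_lo, cfg.grow_hi
            if cfg.invert_first:
                work = segment.invert(work)
                lo, hi = 255 - cfg.grow_hi, 255 - cfg.grow_lo
            work = segment.bilateral_filter_3d(
                work, kernel=cfg.bilateral_kernel, sigma_range=cfg.sigma_range
            )
            record(
                "segment",
                order="invert -> bilateral -> region_grow" if cfg.invert_first
                else "bilateral -> region_grow",
                grow_range=[lo, hi],
                kernel=cfg.bilateral_kernel,
            )
            wall = segment.region_grow(
                work, [cfg.seed_voxel], lo=lo, hi=hi, connectivity=cfg.grow_connectivity
            )
            airway = segment.fill_airway_lumen(wall)
            record(
                "region_grow",
                wall_voxels=int(wall.data.sum()),
                filled_voxels=int(airway.data.sum()),
            )
            io.write_mask(airway, out / "airway_mask.tif")
            mesh = segment.extract_isosurface(airway)
            if mesh.n_faces:
                io.write_mesh(mesh, out / "airway.stl")
        except Exception as e:  # noqa: BLE001
            raise StageError("segment", e) from e

    # ---- morphometry ----------------------------------------------------
    if airway is not None and cfg.run_morphometry:
        try:
            graph = morphometry.skeletonize_airway(
                airway, prune_length=cfg.prune_length, root_hint_um=cfg.root_hint_um
            )
            graph = morphometry.inner_diameter_profile(graph, airway)
            graph = morphometry.assign_generations(graph)
            angles = morphometry.branch_angles(graph, fit_length=cfg.fit_length)
            graph.branch_table().to_csv(out / "branches.csv", index=False)
            morphometry.angles_table(angles).to_csv(out / "angles.csv", index=False)
            record("morphometry", n_branches=graph.n_branches, n_bifurcations=len(angles))
        except Exception as e:  # noqa: BLE001
            raise StageError("morphometry", e) from e

    # ---- quantify -------------------------------------------------------
    report = None
    if cfg.fluorescence_path is not None and cfg.labels_path is not None:
        try:
            fluor = io.read_volume(cfg.fluorescence_path, voxel_size=cfg.voxel_size)
            label_vol = io.read_volume(cfg.labels_path, voxel_size=cfg.voxel_size)
            labels = RegionLabelMap(label_vol.data, label_vol.voxel_size)
            particles = quantify.detect_particles(
                fluor,
                threshold=cfg.detect_threshold,
                min_voxels=cfg.detect_min_voxels,
                single_particle_volume=cfg.single_particle_volume,
            )
            report = quantify.deposition_report(
                particles,
                labels,
                airway_mask=airway,
                surface_distance=cfg.surface_distance,
                density_scale=cfg.density_scale,
            )
            io.write_particles(particles, out / "particles.csv")
            report.to_frame().to_csv(out / "deposition.csv", index=False)
            record(
                "quantify",
                n_particles=len(particles),
                right_left_ratio=report.right_left_ratio,
                acinar_fraction_pct=report.acinar_fraction_pct,
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("quantify", e) from e
    else:
        log.info("fluorescence channel or labels absent: structure-only run, quantify skipped")
        record("quantify", skipped=True)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return report
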