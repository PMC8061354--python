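"""Readers and writers: multi-page TIFF volumes, CSV tables, mesh export.

Volumes are stored as one TIFF page per z-slice (8-bit); the physical
voxel size travels in a JSON sidecar (``<volume>.tif.json``) so that a
round trip is lossless and self-describing. Reading a volume without a
sidecar requires an explicit voxel-size override.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import TileSet
from .types import ParticleSet, SegmentationMask, TriangleMesh, VolumeImage


def write_volume(volume: VolumeImage, path) -> None:
    """Write a volume as multi-page TIFF plus a voxel-size sidecar."""
    path = Path(path)
    data = volume.data
    if not np.issubdtype(data.dtype, np.unsignedinteger):
        data = np.clip(np.rint(data), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data)
    sidecar = {"voxel_size_um": list(volume.voxel_size), "channel": volume.channel}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_volume(path, voxel_size=None, channel=None) -> VolumeImage:
    """Read a multi-page TIFF volume.

    Voxel size comes from the sidecar written by :func:`write_volume`;
    without one, ``voxel_size`` must be given explicitly.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    vs = voxel_size if voxel_size is not None else meta.get("voxel_size_um")
    if vs is None:
        raise ValueError(
            f"no voxel-size metadata found for {path}; pass voxel_size=(z, y, x) µm explicitly"
        )
    ch = channel if channel is not None else meta.get("channel", "structure")
    return VolumeImage(data, tuple(vs), ch)


def write_mask(mask: SegmentationMask, path) -> None:
    """Binary mask as 8-bit TIFF (0/255) with voxel-size sidecar."""
    vol = VolumeImage(mask.data.astype(np.uint8) * 255, mask.voxel_size, "mask")
    write_volume(vol, path)


def read_mask(path, voxel_size=None) -> SegmentationMask:
    vol = read_volume(path, voxel_size=voxel_size)
    return SegmentationMask(vol.data > 0, vol.voxel_size)


def write_mesh(mesh: TriangleMesh, path) -> None:
    """Export a surface mesh as STL or PLY (by file extension)."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(path)


def write_tiles(tiles: TileSet, out_dir, truth=None) -> Path:
    """One TIFF per tile plus a positions CSV (nominal and, if a truth
    ledger is given, true offsets)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (tile, nom) in enumerate(zip(tiles.tiles, tiles.nominal_offsets)):
        tifffile.imwrite(out_dir / f"tile_{i:04d}.tif", tile)
        row = {"tile_id": i, "z0": nom[0], "y0": nom[1], "x0": nom[2]}
        if truth is not None:
            tz, ty, tx = truth.true_offsets[i]
            row.update({"true_z0": int(tz), "true_y0": int(ty), "true_x0": int(tx)})
        rows.append(row)
    pos = out_dir / "positions.csv"
    pd.DataFrame(rows).to_csv(pos, index=False)
    meta = {
        "overlap_fraction": tiles.overlap_fraction,
        "voxel_size_um": list(tiles.voxel_size),
        "channel": tiles.channel,
    }
    (out_dir / "tileset.json").write_text(json.dumps(meta))
    return pos


def read_tiles(tiles_dir, positions_csv=None) -> TileSet:
    tiles_dir = Path(tiles_dir)
    positions_csv = Path(positions_csv) if positions_csv else tiles_dir / "positions.csv"
    pos = pd.read_csv(positions_csv).sort_values("tile_id")
    meta = json.loads((tiles_dir / "tileset.json").read_text())
    tiles = [tifffile.imread(tiles_dir / f"tile_{int(i):04d}.tif") for i in pos["tile_id"]]
    return TileSet(
        tiles=tiles,
        nominal_offsets=pos[["z0", "y0", "x0"]].to_numpy(),
        overlap_fraction=float(meta["overlap_fraction"]),
        voxel_size=tuple(meta["voxel_size_um"]),
        channel=meta.get("channel", "structure"),
    )


def write_particles(particles: ParticleSet, path) -> None:
    particles.particles.to_csv(path, index=False)


def read_particles(path, voxel_size, single_particle_volume=float("nan")) -> ParticleSet:
    df = pd.read_csv(path)
    if "deposition_class" in df.columns:
        df["deposition_class"] = df["deposition_class"].fillna("")
    return ParticleSet(df, voxel_size, single_particle_volume)
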