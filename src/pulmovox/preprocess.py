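"""Mosaic-tile preprocessing: stitching, luminance correction, defect removal.

Serial-sectioning instruments acquire each coronal plane as a grid of
overlapping camera tiles. The preprocessing chain registers the tiles by
normalized cross-correlation on their overlaps (translation only — the
stage is rigid), blends them with a linear feather, divides out smooth
per-slice illumination fields, and interpolates across line defects
(dropped scan rows) detected as robust outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import VolumeImage, _check_voxel_size

log = logging.getLogger(__name__)


@dataclass
class TileSet:
    """A grid of overlapping 3D tiles with nominal placement offsets.

    ``nominal_offsets[i]`` is the (z, y, x) voxel coordinate of tile i's
    origin in the assembled volume, before registration refinement.
    """

    tiles: list[np.ndarray]
    nominal_offsets: np.ndarray
    overlap_fraction: float
    voxel_size: tuple[float, float, float]
    channel: str = "structure"

    def __post_init__(self) -> None:
        self.voxel_size = _check_voxel_size(self.voxel_size)
        self.nominal_offsets = np.asarray(self.nominal_offsets, dtype=int)
        if len(self.tiles) != len(self.nominal_offsets):
            raise ValueError("one nominal offset required per tile")
        shapes = {t.shape for t in self.tiles}
        if len(shapes) > 1:
            raise ValueError(f"tiles must share one shape, got {shapes}")

    @property
    def tile_shape(self) -> tuple[int, int, int]:
        return self.tiles[0].shape


@dataclass
class StitchResult:
    volume: VolumeImage
    offsets: np.ndarray  # refined (z, y, x) voxel offsets, one row per tile
    fallback_tiles: list[int] = field(default_factory=list)


def _feather_weight(shape: tuple[int, int, int]) -> np.ndarray:
    """Separable linear ramp: 1 at the tile border rising toward the centre."""
    ramps = [np.minimum(np.arange(n) + 1, n - np.arange(n)).astype(np.float64) for n in shape]
    return ramps[0][:, None, None] * ramps[1][None, :, None] * ramps[2][None, None, :]


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def stitch_tiles(tiles: TileSet, search_radius: int = 3) -> StitchResult:
    """Assemble tiles into one volume, refining offsets by cross-correlation.

    Tiles are placed in raster order. Each tile's offset is refined within
    ±``search_radius`` voxels of nominal by maximizing the normalized
    cross-correlation against already-placed neighbours over the overlap
    region; overlaps are then blended with a linear feather. If an overlap
    has zero variance (featureless), the nominal offset is kept and a
    warning logged.
    """
    ts = tiles.tile_shape
    noms = tiles.nominal_offsets
    r = int(search_radius)
    lo = noms.min(axis=0)
    hi = (noms + ts).max(axis=0)
    pad = r + 1
    ext_shape = tuple(hi - lo + 2 * pad)

    ref = np.zeros(ext_shape, dtype=np.float64)  # raw placed values (for NCC)
    placed = np.zeros(ext_shape, dtype=bool)
    acc = np.zeros(ext_shape, dtype=np.float64)
    wacc = np.zeros(ext_shape, dtype=np.float64)
    feather = _feather_weight(ts)

    order = np.lexsort((noms[:, 2], noms[:, 1], noms[:, 0]))
    refined = np.zeros_like(noms)
    fallback: list[int] = []

    for count, i in enumerate(order):
        tile = tiles.tiles[i].astype(np.float64)
        base = noms[i] - lo + pad
        if count == 0:
            best = np.zeros(3, dtype=int)
        else:
            best, best_score = np.zeros(3, dtype=int), -np.inf
            found = False
            for dz in range(-r, r + 1):
                for dy in range(-r, r + 1):
                    for dx in range(-r, r + 1):
                        o = base + (dz, dy, dx)
                        sl = tuple(slice(o[k], o[k] + ts[k]) for k in range(3))
                        ov = placed[sl]
                        if ov.sum() < 4:
                            continue
                        score = _ncc(tile[ov], ref[sl][ov])
                        if np.isnan(score):
                            continue
                        found = True
                        if score > best_score:
                            best_score, best = score, np.array((dz, dy, dx))
            if not found:
                log.warning("tile %d: featureless overlap, falling back to nominal offset", i)
                fallback.append(int(i))
                best = np.zeros(3, dtype=int)
        o = base + best
        refined[i] = noms[i] + best
        sl = tuple(slice(o[k], o[k] + ts[k]) for k in range(3))
        acc[sl] += tile * feather
        wacc[sl] += feather
        ref[sl] = tile
        placed[sl] = True

    # crop to the union extent of the placed tiles
    idx = np.argwhere(placed)
    c0, c1 = idx.min(axis=0), idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(c0, c1))
    out = np.zeros(tuple(c1 - c0), dtype=np.float64)
    w = wacc[sl]
    np.divide(acc[sl], w, out=out, where=w > 0)
    dtype = tiles.tiles[0].dtype
    if np.issubdtype(dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(dtype)
    vol = VolumeImage(out, tiles.voxel_size, tiles.channel)
    return StitchResult(volume=vol, offsets=refined, fallback_tiles=fallback)


def correct_illumination(volume: VolumeImage, smoothing_scale: float | None = None) -> VolumeImage:
    """Divide out a smooth per-slice multiplicative gain field.

    The gain field of each z-slice is estimated by large-kernel Gaussian
    smoothing of the slice (sigma = ``smoothing_scale`` µm, default 50× the
    in-plane voxel size) and normalized to unit mean, so division corrects
    luminance non-uniformity without changing the slice mean; the output is
    rescaled to the global input mean. All-zero slices pass unchanged.
    """
    vs = volume.voxel_size
    if smoothing_scale is None:
        smoothing_scale = 50.0 * min(vs[1], vs[2])
    # beyond the slice extent the estimate saturates at (nearly) the slice
    # mean; capping keeps the kernel cost bounded
    ny, nx = volume.data.shape[1:]
    sigma = (min(smoothing_scale / vs[1], ny), min(smoothing_scale / vs[2], nx))
    src = volume.data.astype(np.float64)
    out = np.empty_like(src)
    for z in range(src.shape[0]):
        sl = src[z]
        if not sl.any():
            out[z] = sl
            continue
        gain = ndimage.gaussian_filter(sl, sigma=sigma, mode="reflect")
        gain /= gain.mean()
        np.divide(sl, gain, out=out[z], where=gain > 0)
    in_mean = src.mean()
    out_mean = out.mean()
    if out_mean > 0:
        out *= in_mean / out_mean
    if np.issubdtype(volume.data.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(volume.data.dtype)
    return volume.copy_with(out)


def _flag_outlier_lines(
    means: np.ndarray, z_thresh: float, rel_thresh: float = 0.1
) -> np.ndarray:
    """Modified z-score of line means against a local median trend.

    A line is a defect only if it is both a robust statistical outlier
    (modified z-score > ``z_thresh``) and a substantial relative
    deviation (> ``rel_thresh`` of the local trend) — instrument line
    defects are large multiplicative drops, and the second condition
    keeps ordinary noise fluctuations from being rewritten.
    """
    trend = ndimage.median_filter(means, size=5, mode="reflect")
    d = means - trend
    rel = np.abs(d) / np.maximum(np.abs(trend), 1e-9)
    mad = np.median(np.abs(d - np.median(d)))
    if mad == 0:
        return rel > rel_thresh
    return (np.abs(0.6745 * d / mad) > z_thresh) & (rel > rel_thresh)


def _interp_lines(img: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Replace flagged lines (rows, axis 0) by linear interpolation of clean flanks."""
    good = np.flatnonzero(~bad)
    if good.size == 0:
        return img
    out = img.copy()
    bad_idx = np.flatnonzero(bad)
    for col in range(img.shape[1]):
        out[bad_idx, col] = np.interp(bad_idx, good, img[good, col])
    return out


def remove_defects(
    volume: VolumeImage, defect_z: float = 3.5
) -> tuple[VolumeImage, pd.DataFrame]:
    """Detect and repair line defects (dark/bright scan rows or columns).

    For each z-slice, row and column mean intensities are compared with a
    local median trend; lines whose modified z-score exceeds ``defect_z``
    are replaced by linear interpolation between the nearest clean flanking
    lines. Returns the repaired volume and a table of
    ``(z, axis, index)`` records (axis "y" = row, "x" = column).
    """
    src = volume.data.astype(np.float64)
    out = src.copy()
    records = []
    for z in range(src.shape[0]):
        sl = out[z]
        bad_rows = _flag_outlier_lines(sl.mean(axis=1), defect_z)
        if bad_rows.any():
            out[z] = _interp_lines(sl, bad_rows)
            records += [{"z": z, "axis": "y", "index": int(i)} for i in np.flatnonzero(bad_rows)]
        sl = out[z]
        bad_cols = _flag_outlier_lines(sl.mean(axis=0), defect_z)
        if bad_cols.any():
            out[z] = _interp_lines(sl.T, bad_cols).T
            records += [{"z": z, "axis": "x", "index": int(i)} for i in np.flatnonzero(bad_cols)]
    if np.issubdtype(volume.data.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(volume.data.dtype)
    table = pd.DataFrame(records, columns=["z", "axis", "index"])
    return volume.copy_with(out), table


def enhance_contrast(
    volume: VolumeImage, low_pct: float = 0.5, high_pct: float = 99.5
) -> VolumeImage:
    """Percentile-based linear rescale to the full 8-bit range.

    Maps the ``low_pct``/``high_pct`` intensity percentiles to 0/255 with
    clipping; monotone in the input. A constant volume (degenerate
    percentile range) maps to all zeros.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    src = volume.data.astype(np.float64)
    lo, hi = np.percentile(src, [low_pct, high_pct])
    if hi <= lo:
        out = np.zeros_like(src)
    else:
        out = np.clip((src - lo) / (hi - lo) * 255.0, 0, 255)
    if np.issubdtype(volume.data.dtype, np.integer):
        out = np.rint(out).astype(volume.data.dtype)
    return volume.copy_with(out)


def median_denoise(volume: VolumeImage, radius: int = 1) -> VolumeImage:
    """Small median filter (default radius 1); the heavy denoising is the
    bilateral filter in the segmentation stage."""
    size = 2 * radius + 1
    out = ndimage.median_filter(volume.data, size=size, mode="reflect")
    return volume.copy_with(out)
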