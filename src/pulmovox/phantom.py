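"""Synthetic dual-channel lung phantoms with a machine-readable truth ledger.

The generator emulates, at desk scale, the statistical structure of
whole-lung serial-sectioning data: a monopodial airway tree (a dominant
stem with lateral daughters, the typical murine pattern) whose bright
walls (grey 110–255) stand against darker textured parenchyma (20–100),
vessel tubes, a six-region anatomical partition (five lobes plus the
extrapulmonary trachea), and micron-scale cubic fluorescent particles
placed with configurable per-region volumes and an airway-surface/acinar
split. Companion generators produce overlapping mosaic tiles (with
vignetting, jitter and stripe defects) and cascade-impactor stage-mass
tables from a log-normal aerodynamic distribution.

Every stochastic choice is driven by one seeded generator, so identical
configurations produce bit-identical volumes, and everything the phantom
places is recorded in a :class:`PhantomTruth` ledger for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import lognorm

from .aerosol import NGI_CUTOFFS_65LPM, ImpactorRun
from .preprocess import TileSet
from .types import (
    LOBE_LABELS,
    REGION_LEGEND,
    TRACHEA_LABEL,
    RegionLabelMap,
    SegmentationMask,
    VolumeImage,
)

#: Per-region deposition fractions (%) used as the default particle
#: allocation, ordered by region label 1..6 (five lobes then trachea).
DEFAULT_REGION_FRACTIONS = (27.00, 2.50, 47.05, 3.21, 4.70, 15.52)

#: Default per-lobe particle densities (particle volume / lobe volume at
#: the reporting scale), ordered by lobe label 1..5; together with the
#: fractions these fix the default relative lobe volumes.
DEFAULT_LOBE_DENSITIES = (1.39, 0.53, 3.40, 0.47, 0.65)

_GOLDEN_ANGLE = 137.50776405003785


class PhantomGeometryError(ValueError):
    """A branch cannot be placed inside the volume."""


class PhantomPlacementError(ValueError):
    """A particle quota cannot be honoured with the available space."""


@dataclass
class PhantomConfig:
    """Parameters of the synthetic lung volume.

    Axes are (z, y, x); the airway stem runs along z. Defaults mirror the
    study conditions: 8-bit intensities, airway walls in grey range
    110–255, section voxel 1 µm × in-plane 0.35 µm, cubic particles of
    1.221 µm edge, per-region particle allocations set to the printed
    deposition fractions, and 18.6% of particle volume placed acinar.
    """

    volume_shape: tuple[int, int, int] = (200, 200, 200)
    voxel_size: tuple[float, float, float] = (1.0, 0.35, 0.35)
    tree_mode: str = "monopodial"  # "monopodial" (murine) or "bipodial" (human-like)
    n_generations: int = 3
    root_radius: float = 6.0  # µm, lumen radius of the stem
    wall_thickness: float = 2.0  # µm
    radius_decay: float = 0.6  # per generation
    branch_length: float = 24.0  # µm, first-generation laterals
    length_decay: float = 0.6
    branch_angles: tuple[float, float] = (47.7, 40.0)  # (inter-daughter, parent-deviation) deg
    laterals_per_lobe: int = 2
    wall_intensity_range: tuple[int, int] = (110, 255)
    parenchyma_intensity_range: tuple[int, int] = (20, 100)
    lumen_intensity: int = 8
    region_count: int = 6
    particle_edge: float = 1.221  # µm, cubic particle side
    total_particle_volume: float = 1200.0  # µm³
    per_region_particle_volume: tuple[float, ...] | None = None  # µm³ by label 1..6
    lobe_densities: tuple[float, ...] = DEFAULT_LOBE_DENSITIES
    trachea_rel_volume: float = 8.0  # same f/d units as the lobe weights
    region_rel_volumes: tuple[float, ...] | None = None  # spatial slab weights, labels 1..6
    acinar_fraction: float = 18.6  # % of total particle volume
    acinar_distance: float | None = None  # µm; default 3 × root lumen radius
    cluster_fraction: float = 0.3
    cluster_size_range: tuple[int, int] = (2, 10)
    particle_intensity: int = 230
    noise_sd: float = 12.0  # grey levels, additive Gaussian, both channels
    n_vessels: int = 2
    vessel_radius: float = 3.0  # µm
    background_margin: int = 3  # voxels
    boundary_margin: int = 4  # voxels kept between particles and region faces
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        wlo, whi = self.wall_intensity_range
        plo, phi = self.parenchyma_intensity_range
        if not (phi < wlo or whi < plo):
            raise ValueError("wall and parenchyma intensity ranges must be disjoint")
        if not (0.0 <= self.acinar_fraction <= 100.0):
            raise ValueError("acinar_fraction must lie in [0, 100]")
        if self.region_count != 6:
            raise ValueError("the phantom partitions the lung into exactly 6 regions")
        if self.tree_mode not in ("monopodial", "bipodial"):
            raise ValueError("tree_mode must be 'monopodial' or 'bipodial'")
        if self.per_region_particle_volume is None:
            self.per_region_particle_volume = tuple(
                self.total_particle_volume * f / 100.0 for f in DEFAULT_REGION_FRACTIONS
            )
        self.per_region_particle_volume = tuple(float(v) for v in self.per_region_particle_volume)
        if len(self.per_region_particle_volume) != 6:
            raise ValueError("per_region_particle_volume needs 6 entries (labels 1..6)")
        if any(v < 0 for v in self.per_region_particle_volume):
            raise ValueError("per_region_particle_volume must be non-negative")
        if self.region_rel_volumes is None:
            fr = [v for v in self.per_region_particle_volume[:5]]
            total = sum(self.per_region_particle_volume)
            if total > 0 and len(self.lobe_densities) == 5:
                w = [100.0 * f / total / d for f, d in zip(fr, self.lobe_densities)]
            else:
                w = [1.0] * 5
            self.region_rel_volumes = tuple(w) + (self.trachea_rel_volume,)
        self.region_rel_volumes = tuple(float(v) for v in self.region_rel_volumes)
        if self.acinar_distance is None:
            self.acinar_distance = 3.0 * self.root_radius

    @property
    def particle_block_voxels(self) -> tuple[int, int, int]:
        """Rasterized particle footprint: one cube rounded to whole voxels."""
        return tuple(max(1, int(round(self.particle_edge / v))) for v in self.voxel_size)

    @property
    def particle_quantum(self) -> float:
        """Voxelized volume of one rasterized particle cube (µm³)."""
        return float(np.prod(self.particle_block_voxels)) * float(np.prod(self.voxel_size))


@dataclass
class PhantomTruth:
    """Ground-truth ledger for one generated phantom."""

    airway_mask: SegmentationMask
    region_labels: RegionLabelMap
    lobe_volumes: dict[int, float]
    per_region_particle_volume: dict[int, float]
    acinar_particle_volume: float
    airway_particle_volume: float
    branch_angle_table: list[dict]
    particle_centroids: np.ndarray  # (n, 3) µm, one row per placed component
    particle_component_count: int
    density_scale: float
    airway_seed: tuple[int, int, int]
    illumination_field: np.ndarray | None = None
    config: PhantomConfig | None = None

    def total_particle_volume(self) -> float:
        return float(sum(self.per_region_particle_volume.values()))

    def region_fractions_pct(self) -> dict[int, float]:
        total = self.total_particle_volume()
        if total == 0:
            return {lab: 0.0 for lab in range(1, 7)}
        return {lab: 100.0 * v / total for lab, v in self.per_region_particle_volume.items()}

    def to_ledger(self) -> dict:
        """JSON-compatible summary (masks excluded; write those as TIFF)."""
        return {
            "lobe_volumes_um3": {str(k): v for k, v in self.lobe_volumes.items()},
            "per_region_particle_volume_um3": {
                str(k): v for k, v in self.per_region_particle_volume.items()
            },
            "region_fractions_pct": {str(k): v for k, v in self.region_fractions_pct().items()},
            "acinar_particle_volume_um3": self.acinar_particle_volume,
            "airway_particle_volume_um3": self.airway_particle_volume,
            "acinar_fraction_pct": (
                100.0 * self.acinar_particle_volume / self.total_particle_volume()
                if self.total_particle_volume() > 0
                else 0.0
            ),
            "branch_angle_table": self.branch_angle_table,
            "particle_component_count": self.particle_component_count,
            "particle_centroids_um": np.asarray(self.particle_centroids).tolist(),
            "density_scale": self.density_scale,
            "airway_seed_zyx": list(self.airway_seed),
        }

    def write_ledger(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_ledger(), fh, indent=1)


# ---------------------------------------------------------------------------
# tube rasterization


def rasterize_tube_mask(
    segments: np.ndarray,
    radii: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    cap: str = "flat",
) -> np.ndarray:
    """Boolean mask of a union of tubes around centerline segments.

    ``segments`` is (n, 2, 3): physical (z, y, x) µm endpoints of each
    centerline segment; ``radii`` the per-segment radius in µm. Distances
    are computed in physical units, so anisotropic voxels are handled
    correctly. Each segment is evaluated only inside its bounding box.

    ``cap="flat"`` draws finite cylinders, ``cap="round"`` capsules.
    Flat caps are the default: 3D thinning retracts rounded tube tips
    (the erosion front never forms a curve endpoint), which would make
    terminal branches vanish from the skeleton.
    """
    if cap not in ("flat", "round"):
        raise ValueError("cap must be 'flat' or 'round'")
    segments = np.asarray(segments, dtype=float).reshape(-1, 2, 3)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(segments),))
    vs = np.asarray(voxel_size, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    for (p0, p1), r in zip(segments, radii):
        lo_um = np.minimum(p0, p1) - r - vs
        hi_um = np.maximum(p0, p1) + r + vs
        lo = np.maximum(np.floor(lo_um / vs).astype(int), 0)
        hi = np.minimum(np.ceil(hi_um / vs).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        axes = [(np.arange(lo[k], hi[k]) + 0.5) * vs[k] for k in range(3)]
        Z, Y, X = np.meshgrid(*axes, indexing="ij")
        P = np.stack([Z, Y, X], axis=-1)
        u = p1 - p0
        L2 = float(u @ u)
        if L2 == 0:
            inside = ((P - p0) ** 2).sum(axis=-1) <= r * r
        else:
            t = ((P - p0) @ u) / L2
            tc = np.clip(t, 0.0, 1.0)
            if cap == "round":
                d2 = ((P - p0 - tc[..., None] * u) ** 2).sum(axis=-1)
                inside = d2 <= r * r
            else:
                d2 = ((P - p0 - t[..., None] * u) ** 2).sum(axis=-1)
                inside = (t >= 0.0) & (t <= 1.0) & (d2 <= r * r)
        sub = tuple(slice(lo[k], hi[k]) for k in range(3))
        mask[sub] |= inside
    return mask


# ---------------------------------------------------------------------------
# airway-tree geometry


@dataclass
class _Branch:
    p0: np.ndarray
    p1: np.ndarray
    radius: float
    generation: int


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        w = rng.normal(size=3)
        w -= (w @ u) * u
        n = np.linalg.norm(w)
        if n > 1e-6:
            return w / n


def _build_tree(
    cfg: PhantomConfig, rng: np.random.Generator, slab_bounds: np.ndarray
) -> tuple[list[_Branch], list[dict]]:
    """Monopodial tree: a z-axis stem with lateral daughters in each lobe."""
    vs = np.asarray(cfg.voxel_size)
    size_um = np.asarray(cfg.volume_shape) * vs
    m_um = cfg.background_margin * vs
    # stem axis snapped to an in-plane voxel centre (see rasterize_tube_mask
    # on why boundary-centred tubes defeat 3D thinning)
    yc = (np.floor(size_um[1] / 2.0 / vs[1]) + 0.5) * vs[1]
    xc = (np.floor(size_um[2] / 2.0 / vs[2]) + 0.5) * vs[2]

    wall = cfg.wall_thickness
    z0 = m_um[0] + cfg.root_radius + wall + 1.0
    z1 = size_um[0] - m_um[0] - cfg.root_radius - wall - 1.0
    if cfg.tree_mode == "bipodial":
        # short trachea, then symmetric recursive splitting (human-like)
        z1 = min(z1, z0 + 2.0 * cfg.branch_length)
    stem = _Branch(
        p0=np.array([z0, yc, xc]),
        p1=np.array([z1, yc, xc]),
        radius=cfg.root_radius,
        generation=0,
    )
    branches = [stem]
    angle_table: list[dict] = []

    alpha, theta = (np.deg2rad(a) for a in cfg.branch_angles)
    zhat = np.array([1.0, 0.0, 0.0])

    def inside(p: np.ndarray, r: float) -> bool:
        margin = m_um + r + wall + 1.0
        return bool(np.all(p >= margin) and np.all(p <= size_um - margin))

    def grow(p0: np.ndarray, direction: np.ndarray, gen: int) -> np.ndarray:
        """Place one branch, adjusting direction/length to stay inside.

        If the nominal endpoint escapes the volume, the radial and/or
        axial components are reflected inward and the branch may be
        shortened moderately; the realized direction is returned so the
        truth ledger records the angles actually built.
        """
        length = cfg.branch_length * cfg.length_decay ** (gen - 1)
        radius = cfg.root_radius * cfg.radius_decay**gen
        axial = (direction @ zhat) * zhat
        radial = direction - axial
        trials = [
            _unit(v)
            for v in (
                direction,
                axial - radial,
                radial - axial,
                -direction,
            )
        ]
        placed = None
        for d in trials:
            for scale in (1.0, 0.8, 0.65):
                p1 = p0 + length * scale * d
                if inside(p1, radius):
                    placed = (d, p1)
                    break
            if placed:
                break
        if placed is None:
            raise PhantomGeometryError(
                f"generation {gen} branch escapes the volume near "
                f"{np.round(p0 + length * direction, 1)} µm"
            )
        d, p1 = placed
        branches.append(_Branch(p0=p0.copy(), p1=p1, radius=radius, generation=gen))
        if gen >= cfg.n_generations:
            return d
        w = _perpendicular(d, rng)
        kids = [
            _unit(np.cos(alpha / 2.0) * d + np.sin(alpha / 2.0) * w),
            _unit(np.cos(alpha / 2.0) * d - np.sin(alpha / 2.0) * w),
        ]
        realized = [grow(p1, k, gen + 1) for k in kids]
        angle_table.append(
            {
                "position_um": [float(v) for v in p1],
                "alpha_deg": float(
                    np.rad2deg(np.arccos(np.clip(realized[0] @ realized[1], -1, 1)))
                ),
                "parent_generation": gen,
            }
        )
        return d

    if cfg.tree_mode == "bipodial":
        w = _perpendicular(zhat, rng)
        for sign in (+1.0, -1.0):
            d = _unit(np.cos(alpha / 2.0) * zhat + sign * np.sin(alpha / 2.0) * w)
            grow(stem.p1, d, 1)
        return branches, angle_table

    # lateral daughters in each lobe slab (the trachea slab holds the bare stem)
    k = 0
    for lab in LOBE_LABELS:
        zlo, zhi = slab_bounds[lab]
        zlo_um, zhi_um = zlo * vs[0], zhi * vs[0]
        for j in range(cfg.laterals_per_lobe):
            zb = zlo_um + (j + 0.5) / cfg.laterals_per_lobe * (zhi_um - zlo_um)
            zb += rng.uniform(-1.0, 1.0)
            phi = np.deg2rad(_GOLDEN_ANGLE * k) + rng.uniform(0, 2 * np.pi / 180.0)
            k += 1
            d = _unit(
                np.cos(theta) * zhat
                + np.sin(theta) * np.array([0.0, np.cos(phi), np.sin(phi)])
            )
            grow(np.array([zb, yc, xc]), d, 1)

    return branches, angle_table


def make_bifurcation_phantom(
    alpha_deg: float,
    radius_um: float = 4.0,
    parent_length_um: float = 60.0,
    daughter_length_um: float = 70.0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    margin: int = 6,
) -> tuple[SegmentationMask, dict]:
    """Voxelized Y-branch with a known inter-daughter angle.

    The parent runs along +y into the bifurcation node; the daughters
    leave the node in the y–x plane, split symmetrically by ``alpha_deg``.
    Returns the tube mask and a truth dict with the node position, the
    ground-truth angle and the parent's far endpoint (a root hint for
    skeletonization).
    """
    vs = np.asarray(voxel_size, dtype=float)
    half = np.deg2rad(alpha_deg) / 2.0
    dy = np.array([0.0, 1.0, 0.0])
    d1 = np.array([0.0, np.cos(half), np.sin(half)])
    d2 = np.array([0.0, np.cos(half), -np.sin(half)])
    pad = radius_um + margin
    x_reach = daughter_length_um * np.sin(half)
    node = np.array([pad + radius_um, pad + parent_length_um, pad + x_reach])
    # snap the node onto a voxel centre: axis-aligned tubes whose centerline
    # sits on a voxel boundary have an even-width core that 3D thinning
    # deletes outright
    node = (np.floor(node / vs) + 0.5) * vs
    p_root = node - parent_length_um * dy
    e1 = node + daughter_length_um * d1
    e2 = node + daughter_length_um * d2
    size_um = np.array(
        [2 * (pad + radius_um), node[1] + daughter_length_um + pad, 2 * (pad + x_reach)]
    )
    shape = tuple(int(np.ceil(s / v)) for s, v in zip(size_um, vs))
    segs = np.array([[p_root, node], [node, e1], [node, e2]])
    mask = rasterize_tube_mask(segs, radius_um, shape, tuple(vs))
    truth = {
        "node_um": node,
        "alpha_deg": float(alpha_deg),
        "root_hint_um": p_root,
        "daughter_dirs": np.array([d1, d2]),
    }
    return SegmentationMask(mask, tuple(vs), provenance="make_bifurcation_phantom"), truth


# ---------------------------------------------------------------------------
# region partition


def _region_slabs(cfg: PhantomConfig) -> tuple[np.ndarray, dict[int, tuple[int, int]]]:
    """Partition the interior into z-slabs: trachea first, then the lobes.

    Returns the label volume and per-label (z_lo, z_hi) voxel bounds.
    """
    nz, ny, nx = cfg.volume_shape
    m = cfg.background_margin
    labels = np.zeros(cfg.volume_shape, dtype=np.uint8)
    spatial_order = [TRACHEA_LABEL, *LOBE_LABELS]
    weights = np.array([cfg.region_rel_volumes[lab - 1] for lab in spatial_order], dtype=float)
    edges = m + np.round(np.cumsum(np.concatenate([[0.0], weights])) / weights.sum() * (nz - 2 * m))
    edges = edges.astype(int)
    bounds: dict[int, tuple[int, int]] = {}
    for lab, zlo, zhi in zip(spatial_order, edges[:-1], edges[1:]):
        labels[zlo:zhi, m : ny - m, m : nx - m] = lab
        bounds[lab] = (int(zlo), int(zhi))
    return labels, bounds


# ---------------------------------------------------------------------------
# particle placement

_CLUSTER_OFFSETS = np.array(
    [
        (0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 1, 1),
        (1, 0, 1), (1, 1, 0), (1, 1, 1), (0, 0, -1), (0, -1, 0),
    ]
)


def _place_particles(
    cfg: PhantomConfig,
    rng: np.random.Generator,
    candidates: dict[tuple[int, str], np.ndarray],
    quotas: dict[tuple[int, str], int],
    shape: tuple[int, int, int],
) -> tuple[np.ndarray, list[dict]]:
    """Stamp particle components onto a fluorescence mask.

    ``candidates[(label, cls)]`` are flat voxel indices of admissible
    anchor positions; ``quotas`` the number of particle quanta per
    (region, class). Components (single cubes or compact clusters of up
    to 10 cubes) never touch each other, so each is one connected object
    for the detector, and its volume is an exact multiple of the quantum.
    """
    block = np.asarray(cfg.particle_block_voxels)
    half = block // 2
    fluor = np.zeros(shape, dtype=bool)
    forbidden = np.zeros(shape, dtype=bool)
    components: list[dict] = []
    lo_cap, hi_cap = cfg.cluster_size_range

    for key in sorted(quotas):
        label, cls = key
        need = quotas[key]
        if need <= 0:
            continue
        cand = candidates[key].copy()
        rng.shuffle(cand)
        ptr = 0
        while need > 0:
            size = 1
            if need >= lo_cap and rng.random() < cfg.cluster_fraction:
                size = int(min(rng.integers(lo_cap, hi_cap + 1), need))
            placed = False
            while ptr < len(cand):
                anchor = np.array(np.unravel_index(cand[ptr], shape))
                ptr += 1
                boxes = []
                ok = True
                for off in _CLUSTER_OFFSETS[:size]:
                    c = anchor + off * block
                    lo = c - half
                    hi = lo + block
                    if np.any(lo < 1) or np.any(hi > np.asarray(shape) - 1):
                        ok = False
                        break
                    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
                    if forbidden[sl].any():
                        ok = False
                        break
                    boxes.append(sl)
                if not ok:
                    continue
                vox_centroid = np.zeros(3, dtype=float)
                for sl in boxes:
                    fluor[sl] = True
                    gsl = tuple(slice(s.start - 1, s.stop + 1) for s in sl)
                    forbidden[gsl] = True
                    vox_centroid += np.array([(s.start + s.stop - 1) / 2.0 for s in sl])
                vox_centroid /= size
                centroid_um = (vox_centroid + 0.5) * np.asarray(cfg.voxel_size)
                components.append(
                    {
                        "centroid_um": centroid_um,
                        "region": label,
                        "class": cls,
                        "n_quanta": size,
                    }
                )
                need -= size
                placed = True
                break
            if not placed:
                raise PhantomPlacementError(
                    f"cannot place remaining {need} particle quanta in "
                    f"{REGION_LEGEND[label]} ({cls}): candidate space exhausted"
                )
    return fluor, components


# ---------------------------------------------------------------------------
# main generator


def _smooth_texture(
    rng: np.random.Generator, shape, sigma, lo: float, hi: float
) -> np.ndarray:
    t = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    tmin, tmax = t.min(), t.max()
    if tmax <= tmin:
        return np.full(shape, (lo + hi) / 2.0)
    return lo + (t - tmin) / (tmax - tmin) * (hi - lo)


def generate_lung_phantom(
    config: PhantomConfig,
) -> tuple[VolumeImage, VolumeImage, PhantomTruth]:
    """Generate the structure channel, fluorescence channel and truth ledger.

    Deterministic for a fixed ``config.seed``. Raises
    :class:`PhantomGeometryError` if the configured tree does not fit the
    volume and :class:`PhantomPlacementError` if a particle quota cannot
    be honoured.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.volume_shape)
    vs = np.asarray(cfg.voxel_size)
    voxvol = float(np.prod(vs))

    labels_arr, slab_bounds = _region_slabs(cfg)
    branches, angle_table = _build_tree(cfg, rng, slab_bounds)

    segs = np.array([[b.p0, b.p1] for b in branches])
    lumen_r = np.array([b.radius for b in branches])
    lumen = rasterize_tube_mask(segs, lumen_r, shape, tuple(vs))
    outer = rasterize_tube_mask(segs, lumen_r + cfg.wall_thickness, shape, tuple(vs))
    wall = outer & ~lumen

    # vessels: straight tubes flanking the stem, trimmed to keep a clear
    # 2-voxel gap from the airway so bright walls never connect
    size_um = np.asarray(shape) * vs
    vessel_outer = np.zeros(shape, dtype=bool)
    vessel_lumen = np.zeros(shape, dtype=bool)
    if cfg.n_vessels > 0:
        offs = np.linspace(-0.22, 0.22, cfg.n_vessels) * size_um[1]
        vsegs, vr = [], []
        for o in offs:
            p0 = np.array([cfg.background_margin * vs[0] + 1, size_um[1] / 2 + o, size_um[2] / 2])
            p1 = p0.copy()
            p1[0] = size_um[0] - cfg.background_margin * vs[0] - 1
            vsegs.append([p0, p1])
            vr.append(cfg.vessel_radius)
        vsegs = np.array(vsegs)
        vr = np.array(vr)
        vessel_lumen = rasterize_tube_mask(vsegs, vr, shape, tuple(vs))
        vessel_outer = rasterize_tube_mask(vsegs, vr + 1.5, shape, tuple(vs))
        s26 = ndimage.generate_binary_structure(3, 3)
        exclusion = ndimage.binary_dilation(outer, structure=s26, iterations=2)
        vessel_outer &= ~exclusion
        vessel_lumen &= ~exclusion
    vessel_wall = vessel_outer & ~vessel_lumen

    # structure channel
    interior = labels_arr > 0
    structure = np.zeros(shape, dtype=np.float64)
    plo, phi = cfg.parenchyma_intensity_range
    structure[interior] = _smooth_texture(rng, shape, (1.0, 2.0, 2.0), plo, phi)[interior]
    wall_tex = _smooth_texture(rng, shape, (1.0, 1.5, 1.5), 140.0, 230.0)
    structure[vessel_wall] = wall_tex[vessel_wall]
    structure[vessel_lumen & ~vessel_wall] = cfg.lumen_intensity
    structure[wall] = wall_tex[wall]
    structure[lumen] = cfg.lumen_intensity

    # particle placement
    s26 = ndimage.generate_binary_structure(3, 3)
    outer_shell = ndimage.binary_dilation(outer, structure=s26) & ~outer
    lumen_surface = lumen & ndimage.binary_dilation(wall, structure=s26)
    surface = outer_shell | lumen_surface
    dist_airway = ndimage.distance_transform_edt(~outer, sampling=vs)
    far = dist_airway > cfg.acinar_distance

    bm = cfg.boundary_margin
    m = cfg.background_margin
    in_bounds = np.zeros(shape, dtype=bool)
    in_bounds[m + 2 : shape[0] - m - 2, m + 2 : shape[1] - m - 2, m + 2 : shape[2] - m - 2] = True

    quantum = cfg.particle_quantum
    req = np.asarray(cfg.per_region_particle_volume)
    total_req = req.sum()
    lobe_req = req[:5].sum()
    quotas: dict[tuple[int, str], int] = {}
    candidates: dict[tuple[int, str], np.ndarray] = {}
    for lab in range(1, 7):
        v_r = req[lab - 1]
        if lab == TRACHEA_LABEL or lobe_req == 0:
            v_acinar = 0.0
        else:
            v_acinar = (cfg.acinar_fraction / 100.0) * total_req * (v_r / lobe_req)
            v_acinar = min(v_acinar, v_r)
        q_total = int(round(v_r / quantum)) if quantum > 0 else 0
        q_acinar = int(round(v_acinar / quantum)) if quantum > 0 else 0
        q_acinar = min(q_acinar, q_total)
        zlo, zhi = slab_bounds[lab]
        slab = np.zeros(shape, dtype=bool)
        zl = max(zlo + bm, 0)
        zh = min(zhi - bm, shape[0])
        if zl < zh:
            slab[zl:zh] = True
        region_ok = slab & in_bounds
        quotas[(lab, "airway")] = q_total - q_acinar
        quotas[(lab, "acinar")] = q_acinar
        candidates[(lab, "airway")] = np.flatnonzero(surface & region_ok)
        candidates[(lab, "acinar")] = np.flatnonzero(far & region_ok & ~vessel_outer)

    fluor_mask, components = _place_particles(cfg, rng, candidates, quotas, shape)

    fluorescence = np.zeros(shape, dtype=np.float64)
    fluorescence[fluor_mask] = cfg.particle_intensity

    if cfg.noise_sd > 0:
        structure += rng.normal(0.0, cfg.noise_sd, shape)
        fluorescence += rng.normal(0.0, cfg.noise_sd, shape)
    structure_u8 = np.clip(np.rint(structure), 0, 255).astype(np.uint8)
    fluor_u8 = np.clip(np.rint(fluorescence), 0, 255).astype(np.uint8)

    # truth bookkeeping
    per_region_vol = {
        lab: float((fluor_mask & (labels_arr == lab)).sum()) * voxvol for lab in range(1, 7)
    }
    acinar_vol = quantum * sum(q for (lab, c), q in quotas.items() if c == "acinar")
    airway_vol = quantum * sum(q for (lab, c), q in quotas.items() if c == "airway")
    region_map = RegionLabelMap(labels_arr, tuple(vs))
    lobe_volumes = region_map.region_volumes()

    # self-consistent density reporting scale, derived from the build:
    # the scale that maps (placed volume / lobe volume) onto the density
    # units in which the lobe allocations were specified
    dens_terms = []
    for lab in LOBE_LABELS:
        if req[lab - 1] > 0 and len(cfg.lobe_densities) == 5:
            dens_terms.append(
                cfg.lobe_densities[lab - 1] * lobe_volumes[lab] / req[lab - 1]
            )
    if dens_terms:
        density_scale = float(np.mean(dens_terms))
    else:
        lv = sum(lobe_volumes[lab] for lab in LOBE_LABELS)
        pv = max(req[:5].sum(), 1e-12)
        density_scale = float(lv / pv)

    # seed voxel for region growing: a wall voxel whose *noisy* value is
    # inside the wall grey range, nearest the stem origin
    wlo, whi = cfg.wall_intensity_range
    seed_cand = wall & (structure_u8 >= wlo) & (structure_u8 <= whi)
    idx = np.argwhere(seed_cand)
    if len(idx) == 0:
        raise PhantomGeometryError("no in-range wall voxel available as a seed")
    seed_vox = tuple(int(c) for c in idx[np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))][0])

    truth = PhantomTruth(
        airway_mask=SegmentationMask(outer, tuple(vs), provenance="phantom airway (lumen+wall)"),
        region_labels=region_map,
        lobe_volumes=lobe_volumes,
        per_region_particle_volume=per_region_vol,
        acinar_particle_volume=float(acinar_vol),
        airway_particle_volume=float(airway_vol),
        branch_angle_table=angle_table,
        particle_centroids=(
            np.array([c["centroid_um"] for c in components]).reshape(-1, 3)
        ),
        particle_component_count=len(components),
        density_scale=density_scale,
        airway_seed=seed_vox,
        config=cfg,
    )
    structure_img = VolumeImage(structure_u8, tuple(vs), "structure")
    fluor_img = VolumeImage(fluor_u8, tuple(vs), "fluorescence")
    return structure_img, fluor_img, truth


# ---------------------------------------------------------------------------
# mosaic tiles


@dataclass
class TileTruth:
    """Ground truth for a generated tile set."""

    true_offsets: np.ndarray  # (n, 3) voxel offsets actually cropped at
    vignette_strength: float
    stripes: list[dict]  # {tile, z, y} multiplicative gain-0.2 rows
    vignette_field: np.ndarray  # (ny, nx) in-plane gain applied to every tile

    def to_ledger(self) -> dict:
        return {
            "true_offsets": self.true_offsets.tolist(),
            "vignette_strength": self.vignette_strength,
            "stripes": self.stripes,
        }


def vignette_field(tile_yx: tuple[int, int], strength: float) -> np.ndarray:
    """Radial multiplicative gain: 1 at the tile centre, 1-strength at corners."""
    ny, nx = tile_yx
    ry = np.linspace(-1.0, 1.0, ny)[:, None]
    rx = np.linspace(-1.0, 1.0, nx)[None, :]
    return 1.0 - strength * (ry**2 + rx**2) / 2.0


def _grid_starts(n: int, tile: int, step: int) -> list[int]:
    starts = list(range(0, max(n - tile, 0) + 1, step))
    if starts[-1] != n - tile:
        starts.append(n - tile)
    return starts


def generate_tiles(
    volume: VolumeImage,
    tile_shape: tuple[int, int, int],
    overlap_fraction: float = 0.1,
    jitter_px: int = 0,
    vignette_strength: float = 0.0,
    stripe_prob: float = 0.0,
    seed: int = 0,
) -> tuple[TileSet, TileTruth]:
    """Cut a volume into overlapping tiles with stage jitter and shading.

    Each tile is cropped at ``nominal + jitter`` (jitter uniform in
    ±``jitter_px`` per axis, clipped to stay inside the volume), multiplied
    by a radial vignette of the given strength, and — with probability
    ``stripe_prob`` per tile — scarred by one gain-0.2 row defect at a
    recorded (z, y) position.
    """
    if not (0.0 < overlap_fraction < 0.5):
        raise ValueError("overlap_fraction must lie in (0, 0.5)")
    shape = volume.shape
    tile_shape = tuple(int(t) for t in tile_shape)
    if any(t > n for t, n in zip(tile_shape, shape)):
        raise ValueError(f"tile shape {tile_shape} exceeds volume shape {shape}")
    rng = np.random.default_rng(seed)
    steps = [max(1, int(round(t * (1.0 - overlap_fraction)))) for t in tile_shape]
    starts = [_grid_starts(n, t, s) for n, t, s in zip(shape, tile_shape, steps)]

    field = vignette_field(tile_shape[1:], vignette_strength)
    tiles, noms, trues, stripes = [], [], [], []
    tid = 0
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                nom = np.array([z0, y0, x0])
                # tile 0 is the stage origin: offsets are defined relative
                # to it, so it carries no jitter of its own
                if jitter_px and tid > 0:
                    jit = rng.integers(-jitter_px, jitter_px + 1, size=3)
                else:
                    jit = np.zeros(3, int)
                true = np.clip(nom + jit, 0, np.asarray(shape) - np.asarray(tile_shape))
                crop = volume.data[
                    true[0] : true[0] + tile_shape[0],
                    true[1] : true[1] + tile_shape[1],
                    true[2] : true[2] + tile_shape[2],
                ].astype(np.float64)
                crop = crop * field[None, :, :]
                if stripe_prob > 0 and rng.random() < stripe_prob:
                    sz = int(rng.integers(0, tile_shape[0]))
                    sy = int(rng.integers(0, tile_shape[1]))
                    crop[sz, sy, :] *= 0.2
                    stripes.append({"tile": tid, "z": sz, "y": sy})
                if np.issubdtype(volume.data.dtype, np.integer):
                    crop = np.clip(np.rint(crop), 0, 255).astype(volume.data.dtype)
                tiles.append(crop)
                noms.append(nom)
                trues.append(true)
                tid += 1
    tileset = TileSet(
        tiles=tiles,
        nominal_offsets=np.array(noms),
        overlap_fraction=overlap_fraction,
        voxel_size=volume.voxel_size,
        channel=volume.channel,
    )
    truth = TileTruth(
        true_offsets=np.array(trues),
        vignette_strength=vignette_strength,
        stripes=stripes,
        vignette_field=field,
    )
    return tileset, truth


# ---------------------------------------------------------------------------
# impactor runs


def generate_impactor_run(
    mmad: float,
    gsd: float,
    cutoffs=NGI_CUTOFFS_65LPM,
    total_mass: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> ImpactorRun:
    """Stage masses of a log-normal aerodynamic mass distribution.

    Stage *i* receives ``total_mass × (F(c_{i-1}) − F(c_i))`` where F is
    the log-normal mass CDF (median ``mmad``, geometric SD ``gsd``); the
    top stage collects everything above the first cutoff and the collector
    everything below the last. ``gsd == 1`` is the monodisperse limit
    (all mass on the interval containing ``mmad``). Optional multiplicative
    Gaussian noise with coefficient of variation ``noise_cv``.
    """
    if gsd < 1.0:
        raise ValueError(f"gsd must be >= 1, got {gsd}")
    if mmad <= 0:
        raise ValueError("mmad must be positive")
    cutoffs = np.asarray(cutoffs, dtype=float)
    if np.any(cutoffs <= 0) or np.any(np.diff(cutoffs) >= 0):
        raise ValueError("cutoffs must be positive and strictly decreasing")
    if gsd == 1.0:
        cdf = lambda d: (np.asarray(d, dtype=float) > mmad).astype(float)  # noqa: E731
    else:
        dist = lognorm(s=np.log(gsd), scale=mmad)
        cdf = dist.cdf
    F = cdf(cutoffs)
    upper = np.concatenate([[1.0], F[:-1]])
    stage_masses = total_mass * (upper - F)
    collector = total_mass * F[-1]
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        factors = np.clip(rng.normal(1.0, noise_cv, size=len(stage_masses) + 1), 0.0, None)
        stage_masses = stage_masses * factors[:-1]
        collector = collector * factors[-1]
    return ImpactorRun(
        cutoffs=cutoffs,
        stage_masses=stage_masses,
        collector_mass=float(collector),
        flow_rate_lpm=65.0,
    )
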