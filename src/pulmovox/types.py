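"""Core in-memory containers shared across the pipeline stages.

All volumes are ``(z, y, x)``-ordered numpy arrays with per-axis physical
voxel sizes in micrometres, matching the serial-sectioning convention in
which ``z`` is the (usually coarser) section axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Anatomical region legend used throughout: five lung lobes plus the
#: extrapulmonary trachea; 0 is background (outside the lung).
REGION_LEGEND = {
    0: "background",
    1: "left lobe",
    2: "accessory lobe",
    3: "right caudal lobe",
    4: "right middle lobe",
    5: "right cranial lobe",
    6: "extrapulmonary trachea",
}

#: Labels counted on the "right" side of the lung (everything except the
#: left lobe; the extrapulmonary trachea belongs to neither side).
RIGHT_LABELS = (2, 3, 4, 5)
LEFT_LABEL = 1
TRACHEA_LABEL = 6
LOBE_LABELS = (1, 2, 3, 4, 5)


def _check_voxel_size(voxel_size) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be 3 positive lengths (µm), got {voxel_size}")
    return vs


@dataclass
class VolumeImage:
    """A 3D scalar image with physical voxel size and a channel tag.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        8-bit intensities (values in [0, 255]).
    voxel_size : (float, float, float)
        Physical voxel edge lengths (z, y, x) in µm; anisotropy allowed.
    channel : str
        Either ``"structure"`` (tissue stain) or ``"fluorescence"``
        (particle channel).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = "structure"

    def __post_init__(self) -> None:
        self.voxel_size = _check_voxel_size(self.voxel_size)
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        return float(np.prod(self.voxel_size))

    def copy_with(self, data: np.ndarray) -> "VolumeImage":
        return VolumeImage(data, self.voxel_size, self.channel)


@dataclass
class SegmentationMask:
    """Boolean voxel mask plus the provenance of the operation that made it."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: str = ""
    connectivity: int = 6

    def __post_init__(self) -> None:
        self.voxel_size = _check_voxel_size(self.voxel_size)
        self.data = np.asarray(self.data, dtype=bool)
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def volume_um3(self) -> float:
        """Physical volume of the mask: voxel count × voxel volume."""
        return float(self.data.sum()) * self.voxel_volume


@dataclass
class RegionLabelMap:
    """Integer volume assigning voxels to anatomical regions (see REGION_LEGEND)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxel_size = _check_voxel_size(self.voxel_size)
        self.data = np.asarray(self.data)
        bad = set(np.unique(self.data)) - set(REGION_LEGEND)
        if bad:
            raise ValueError(f"unknown region labels {sorted(bad)}")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def region_volumes(self) -> dict[int, float]:
        """Physical volume (µm³) per region label, background excluded."""
        counts = np.bincount(self.data.ravel(), minlength=7)
        return {lab: float(counts[lab]) * self.voxel_volume for lab in range(1, 7)}


@dataclass
class TriangleMesh:
    """Triangulated surface with vertices in physical µm coordinates."""

    vertices: np.ndarray  # (n, 3) float, µm, (z, y, x) order
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)


PARTICLE_COLUMNS = [
    "id",
    "z_um",
    "y_um",
    "x_um",
    "voxel_count",
    "volume_um3",
    "region",
    "deposition_class",
    "is_cluster",
]


@dataclass
class ParticleSet:
    """Detected fluorescent objects, one row per connected component.

    ``particles`` is a DataFrame with columns ``id, z_um, y_um, x_um,
    voxel_count, volume_um3, region, deposition_class, is_cluster``.
    ``region`` is -1 until regions are assigned (and stays -1 for
    particles that could not be rescued onto a labelled voxel);
    ``deposition_class`` is "" until classified ("airway" or "acinar").
    """

    particles: pd.DataFrame
    voxel_size: tuple[float, float, float]
    single_particle_volume: float = float("nan")

    def __post_init__(self) -> None:
        self.voxel_size = _check_voxel_size(self.voxel_size)
        missing = [c for c in PARTICLE_COLUMNS if c not in self.particles.columns]
        if missing:
            raise ValueError(f"particle table missing columns {missing}")

    def __len__(self) -> int:
        return len(self.particles)

    def total_volume(self) -> float:
        return float(self.particles["volume_um3"].sum())

    @staticmethod
    def empty(voxel_size, single_particle_volume=float("nan")) -> "ParticleSet":
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            PARTICLE_COLUMNS,
            [int, float, float, float, int, float, int, str, bool],
        )})
        return ParticleSet(df, voxel_size, single_particle_volume)


@dataclass
class DepositionReport:
    """Region-wise deposition summary of one particle set.

    fraction_pct
        Percent of total assigned particle volume per region (sums to 100).
    density
        Particle volume / region volume × scale, five lobes only.
    right_left_ratio
        (accessory + right caudal + right middle + right cranial) / left,
        extrapulmonary trachea excluded from both sides.
    acinar_fraction_pct
        Percent of particle volume classified acinar (by volume); the
        count-based figure is reported alongside.
    """

    fraction_pct: dict[int, float]
    density: dict[int, float]
    right_left_ratio: float
    acinar_fraction_pct: float
    acinar_fraction_count_pct: float = float("nan")
    cluster_histogram: dict | None = None
    n_unassigned: int = 0
    parameters: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab in range(1, 7):
            rows.append(
                {
                    "region": lab,
                    "region_name": REGION_LEGEND[lab],
                    "fraction_pct": self.fraction_pct.get(lab, 0.0),
                    "density": self.density.get(lab, float("nan")),
                }
            )
        return pd.DataFrame(rows)
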