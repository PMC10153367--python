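"""Voxel grids, binary label volumes, NIfTI I/O and applicator geometry.

Conventions used throughout the package:

* world coordinates are in millimetres; voxel indices are 0-based;
* ``world(index) = origin + index * spacing`` gives the *center* of a voxel;
* a voxel belongs to a region iff its center lies in the region;
* all volumes are reoriented to the canonical (RAS) axis order on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np

from . import constants

MASK_ROLES = ("liver", "vessel", "ablation_gt", "ablation_pred", "applicator")


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along each axis, all >= 1.
    spacing
        Voxel edge length per axis in mm, all > 0.
    origin
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel indices to world mm."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (nx,1,1)/(1,ny,1)/(1,1,nz) world-coordinate arrays."""
        ax = self.world_axes()
        return (
            ax[0][:, None, None],
            ax[1][None, :, None],
            ax[2][None, None, :],
        )

    def center(self) -> np.ndarray:
        """World coordinate of the grid center."""
        return self.index_to_world((np.asarray(self.shape) - 1) / 2.0)

    def subgrid(self, lo: Iterable[int], hi: Iterable[int]) -> "VoxelGrid":
        """Grid covering voxel index range [lo, hi) of this grid."""
        lo = np.asarray(list(lo), dtype=int)
        hi = np.asarray(list(hi), dtype=int)
        if np.any(lo < 0) or np.any(hi > self.shape) or np.any(hi <= lo):
            raise ValueError(f"invalid subgrid range {lo}..{hi} for shape {self.shape}")
        return VoxelGrid(
            shape=tuple(hi - lo),
            spacing=self.spacing,
            origin=tuple(self.index_to_world(lo)),
        )


@dataclass
class LabelVolume:
    """Binary mask on a :class:`VoxelGrid` with a semantic role."""

    grid: VoxelGrid
    voxels: np.ndarray
    role: str = "ablation_pred"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.dtype != bool:
            if not np.isin(self.voxels, (0, 1)).all():
                raise ValueError("voxels must be strictly binary")
            self.voxels = self.voxels.astype(bool)
        if tuple(self.voxels.shape) != self.grid.shape:
            raise ValueError(
                f"voxel array shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {MASK_ROLES}")

    @property
    def n_true(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_true * self.grid.voxel_volume_ml

    @property
    def volume_mm3(self) -> float:
        return self.n_true * self.grid.voxel_volume_mm3

    def with_voxels(self, voxels: np.ndarray) -> "LabelVolume":
        return LabelVolume(grid=self.grid, voxels=voxels, role=self.role)


@dataclass(frozen=True)
class ApplicatorPose:
    """Needle applicator pose: tip position plus insertion direction.

    The active zone is the cylinder segment extending *proximally* from the
    tip, i.e. from ``tip`` to ``tip - direction * active_zone_length``.
    """

    tip: tuple[float, float, float]
    direction: tuple[float, float, float]
    active_zone_length: float = constants.ACTIVE_ZONE_LENGTH_MM
    shaft_radius: float = constants.SHAFT_RADIUS_MM

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector, |d| = {n}")
        if self.active_zone_length <= 0:
            raise ValueError("active_zone_length must be > 0")
        if self.shaft_radius <= 0:
            raise ValueError("shaft_radius must be > 0")
        object.__setattr__(self, "tip", tuple(float(x) for x in self.tip))
        object.__setattr__(self, "direction", tuple(float(x) for x in d))

    @property
    def zone_end(self) -> np.ndarray:
        """Proximal end of the active zone."""
        return np.asarray(self.tip) - np.asarray(self.direction) * self.active_zone_length

    @property
    def zone_midpoint(self) -> np.ndarray:
        return np.asarray(self.tip) - np.asarray(self.direction) * (self.active_zone_length / 2.0)


@dataclass(frozen=True)
class AblationSetting:
    """One microwave activation: generator power and duration."""

    power: float    # W
    duration: float  # s

    def __post_init__(self):
        if self.power <= 0:
            raise ValueError("power must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @classmethod
    def from_minutes(cls, power_w: float, duration_min: float) -> "AblationSetting":
        return cls(power=power_w, duration=duration_min * 60.0)


def segment_geometry(
    grid: VoxelGrid, start: np.ndarray, end: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Axial and radial distance of every voxel center to the segment [start, end].

    Returns
    -------
    axial_outside : (nx,ny,nz) array
        Distance along the axis beyond either segment endpoint (0 for points
        whose projection falls inside the segment).
    radial : (nx,ny,nz) array
        Distance to the (infinite) axis line.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    axis = end - start
    length = float(np.linalg.norm(axis))
    if length <= 0:
        raise ValueError("degenerate (zero-length) segment")
    axis = axis / length
    x, y, z = grid.coordinate_arrays()
    dx = x - start[0]
    dy = y - start[1]
    dz = z - start[2]
    s = dx * axis[0] + dy * axis[1] + dz * axis[2]
    d2 = dx * dx + dy * dy + dz * dz
    radial = np.sqrt(np.maximum(d2 - s * s, 0.0))
    axial_outside = np.maximum(np.maximum(-s, s - length), 0.0)
    return axial_outside, radial


def segment_distance(grid: VoxelGrid, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Euclidean distance of every voxel center to the segment [start, end]."""
    axial, radial = segment_geometry(grid, start, end)
    return np.sqrt(axial * axial + radial * radial)


def rasterize_active_zone(pose: ApplicatorPose, grid: VoxelGrid) -> LabelVolume:
    """Mask of voxels whose centers lie within ``shaft_radius`` of the active zone."""
    dist = segment_distance(grid, pose.zone_end, np.asarray(pose.tip))
    voxels = dist <= pose.shaft_radius
    if not voxels.any():
        raise ValueError("active zone does not intersect the grid")
    return LabelVolume(grid=grid, voxels=voxels, role="applicator")


def _grid_from_nifti(img: nib.Nifti1Image) -> tuple[VoxelGrid, np.ndarray]:
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim} dimensions")
    data = np.asarray(data, dtype=float)
    if not np.isfinite(data).all():
        raise ValueError("volume contains non-finite voxel values")
    aff = img.affine
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(aff))
    origin = tuple(float(t) for t in aff[:3, 3])
    grid = VoxelGrid(shape=data.shape, spacing=spacing, origin=origin)
    return grid, data


def read_mask(path: str | Path, expected_role: str = "ablation_pred") -> LabelVolume:
    """Read a binary mask from a NIfTI file; any nonzero voxel becomes True."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    grid, data = _grid_from_nifti(nib.load(str(path)))
    return LabelVolume(grid=grid, voxels=data != 0, role=expected_role)


def write_mask(mask: LabelVolume, path: str | Path) -> None:
    """Write a binary mask as uint8 NIfTI; round-trips bit-exactly."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine)
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


def read_scalar_field(path: str | Path) -> tuple[VoxelGrid, np.ndarray]:
    """Read a scalar NIfTI volume (temperature, damage) with its grid."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _grid_from_nifti(nib.load(str(path)))


def write_scalar_field(grid: VoxelGrid, values: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
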