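"""Arrhenius thermal damage accumulation and ablation-mask extraction.

Cumulative injury is the first-order Arrhenius integral

    Omega(x) = int_0^t A * exp(-E_a / (R * T_K(x, t'))) dt',

and the predicted ablation is the region where Omega exceeds a threshold
(default Omega* = 1, ~63% cell death). Sequential ablations are treated as
independent and their masks united.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import constants
from .bioheat import TemperatureField, TissueProperties, damage_rate
from .volumes import LabelVolume, VoxelGrid


@dataclass
class DamageField:
    """Accumulated (dimensionless) Arrhenius damage Omega per voxel."""

    grid: VoxelGrid
    omega: np.ndarray

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        if tuple(self.omega.shape) != self.grid.shape:
            raise ValueError("omega shape does not match grid")
        if (self.omega < 0).any():
            raise ValueError("Omega must be non-negative")

    @classmethod
    def zeros(cls, grid: VoxelGrid) -> "DamageField":
        return cls(grid=grid, omega=np.zeros(grid.shape))


def accumulate(
    damage: DamageField,
    snapshots: list[TemperatureField],
    props: TissueProperties,
) -> DamageField:
    """Add trapezoidal Arrhenius damage over time-ordered temperature snapshots."""
    times = [s.time for s in snapshots]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError(f"snapshot timestamps must be strictly increasing, got {times}")
    omega = damage.omega.copy()
    for prev, curr in zip(snapshots, snapshots[1:]):
        if prev.grid.shape != damage.grid.shape:
            raise ValueError("snapshot grid mismatch")
        dt = curr.time - prev.time
        omega += 0.5 * (damage_rate(prev.values, props) + damage_rate(curr.values, props)) * dt
    return DamageField(grid=damage.grid, omega=omega)


@dataclass
class ComponentReport:
    n_components: int
    sizes_voxels: list[int]


def ablation_mask(
    damage: DamageField, threshold: float = constants.OMEGA_THRESHOLD
) -> tuple[LabelVolume, ComponentReport]:
    """Voxels with Omega >= threshold, with a connected-component report."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    voxels = damage.omega >= threshold
    labels, n = ndimage.label(voxels)
    sizes = ndimage.sum_labels(voxels, labels, index=range(1, n + 1)) if n else []
    report = ComponentReport(n_components=int(n), sizes_voxels=[int(s) for s in sizes])
    return LabelVolume(grid=damage.grid, voxels=voxels, role="ablation_pred"), report


def cem43(snapshots: list[TemperatureField]) -> np.ndarray:
    """Auxiliary CEM43 thermal dose (equivalent minutes at 43 C) per voxel.

    Uses the standard piecewise base (0.25 below 43 C, 0.5 above); provided
    for comparison only — the package's ablation criterion is the Arrhenius
    Omega threshold.
    """
    times = [s.time for s in snapshots]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("snapshot timestamps must be strictly increasing")
    dose = np.zeros(snapshots[0].values.shape)
    for prev, curr in zip(snapshots, snapshots[1:]):
        dt_min = (curr.time - prev.time) / 60.0
        t_mid = 0.5 * (prev.values + curr.values)
        base = np.where(t_mid >= 43.0, 0.5, 0.25)
        dose += dt_min * base ** (43.0 - t_mid)
    return dose


def union_sequential(masks: list[LabelVolume]) -> LabelVolume:
    """Voxelwise OR of per-ablation masks (sequential ablations independent)."""
    if not masks:
        raise ValueError("no masks to unite")
    grid = masks[0].grid
    voxels = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        if m.grid.shape != grid.shape or m.grid.spacing != grid.spacing:
            raise ValueError("all masks must share one grid")
        voxels |= m.voxels
    return LabelVolume(grid=grid, voxels=voxels, role=masks[0].role)
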