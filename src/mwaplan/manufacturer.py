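"""Manufacturer-tabulated ablation dimensions and the ellipsoid baseline.

Vendors publish expected ablation length/diameter per (power, duration)
setting, typically measured ex vivo. This module interpolates such a table
and rasterizes the corresponding prolate-ellipsoid prediction around the
applicator — the comparison baseline for the biophysical model and the
"representative ablation volume" used by the vascular-fraction metric.

The table shipped with the package (``data/manufacturer_table_synthetic.csv``)
is *synthetic*: it was generated with this package's own simulator at a fixed
reference source model, because real vendor tables are proprietary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator

from .volumes import AblationSetting, ApplicatorPose, LabelVolume, VoxelGrid


class TableRangeError(ValueError):
    """Query outside the (power, time) range covered by the table."""


@dataclass(frozen=True)
class ManufacturerTable:
    """Rows of (power W, time s, ablation length mm, ablation diameter mm)."""

    rows: pd.DataFrame  # columns power_w, time_s, length_mm, diameter_mm

    def __post_init__(self):
        df = self.rows
        required = ["power_w", "time_s", "length_mm", "diameter_mm"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"table missing columns {missing}")
        if len(df) == 0:
            raise ValueError("empty manufacturer table")
        if (df[required] <= 0).any().any():
            raise ValueError("all table entries must be > 0")
        if df.duplicated(subset=["power_w", "time_s"]).any():
            raise ValueError("duplicate (power, time) rows")
        if (df["length_mm"] < df["diameter_mm"]).any():
            raise ValueError("prolate convention violated: length < diameter")

    @classmethod
    def from_records(cls, records) -> "ManufacturerTable":
        """Build from (power_w, time_s, length_mm, diameter_mm) tuples."""
        return cls(pd.DataFrame(records, columns=["power_w", "time_s", "length_mm", "diameter_mm"]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ManufacturerTable":
        """Load a CSV with header power_W,time_min,length_mm,diameter_mm."""
        df = pd.read_csv(path, comment="#")
        df.columns = [c.strip().lower() for c in df.columns]
        df = df.rename(columns={"power_w": "power_w", "time_min": "time_min"})
        if "time_min" in df.columns:
            df["time_s"] = df["time_min"] * 60.0
            df = df.drop(columns=["time_min"])
        return cls(df[["power_w", "time_s", "length_mm", "diameter_mm"]])

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        out = self.rows.copy()
        out["time_min"] = out["time_s"] / 60.0
        out = out[["power_w", "time_min", "length_mm", "diameter_mm"]]
        out.columns = ["power_W", "time_min", "length_mm", "diameter_mm"]
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            out.to_csv(fh, index=False)

    @property
    def powers(self) -> np.ndarray:
        return np.sort(self.rows["power_w"].unique())

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.rows["time_s"].unique())

    def is_rectangular(self) -> bool:
        return len(self.rows) == len(self.powers) * len(self.times)


def load_default_table() -> ManufacturerTable:
    """The synthetic table bundled with the package (see module docstring)."""
    ref = importlib.resources.files("mwaplan").joinpath(
        "data/manufacturer_table_synthetic.csv"
    )
    with importlib.resources.as_file(ref) as p:
        return ManufacturerTable.from_csv(p)


def lookup_dimensions(
    table: ManufacturerTable, setting: AblationSetting
) -> tuple[float, float]:
    """Bilinearly interpolate (length, diameter) mm at the given setting.

    Raises :class:`TableRangeError` outside the tabulated (power, time) range;
    extrapolation beyond vendor data is never performed.
    """
    p, t = setting.power, setting.duration
    df = table.rows
    if table.is_rectangular():
        powers, times = table.powers, table.times
        if not (powers[0] <= p <= powers[-1] and times[0] <= t <= times[-1]):
            raise TableRangeError(
                f"setting ({p} W, {t} s) outside table range "
                f"[{powers[0]}, {powers[-1]}] W x [{times[0]}, {times[-1]}] s"
            )
        grid_vals = (
            df.set_index(["power_w", "time_s"])
            .sort_index()[["length_mm", "diameter_mm"]]
            .to_numpy()
            .reshape(len(powers), len(times), 2)
        )
        itp = RegularGridInterpolator((powers, times), grid_vals, method="linear")
        length, diameter = itp((p, t))
    else:
        pts = df[["power_w", "time_s"]].to_numpy()
        itp = LinearNDInterpolator(pts, df[["length_mm", "diameter_mm"]].to_numpy())
        length, diameter = np.atleast_2d(itp(p, t))[0]
        if np.isnan(length) or np.isnan(diameter):
            raise TableRangeError(f"setting ({p} W, {t} s) outside the table convex hull")
    return float(length), float(diameter)


@dataclass(frozen=True)
class EllipsoidSpec:
    """Prolate ellipsoid: semi-axes (length/2, diameter/2, diameter/2)."""

    center: tuple[float, float, float]
    long_axis_direction: tuple[float, float, float]
    length: float
    diameter: float

    def __post_init__(self):
        d = np.asarray(self.long_axis_direction, dtype=float)
        n = float(np.linalg.norm(d))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"long_axis_direction must be a unit vector, |d| = {n}")
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("length and diameter must be > 0")

    @property
    def volume_mm3(self) -> float:
        return (4.0 / 3.0) * np.pi * (self.length / 2) * (self.diameter / 2) ** 2


def ellipsoid_mask(spec: EllipsoidSpec, grid: VoxelGrid) -> LabelVolume:
    """Voxels whose centers satisfy the rotated-ellipsoid inequality."""
    c = np.asarray(spec.center, dtype=float)
    d = np.asarray(spec.long_axis_direction, dtype=float)
    a = spec.length / 2.0
    b = spec.diameter / 2.0
    x, y, z = grid.coordinate_arrays()
    ux = x - c[0]
    uy = y - c[1]
    uz = z - c[2]
    par = ux * d[0] + uy * d[1] + uz * d[2]
    perp2 = np.maximum(ux * ux + uy * uy + uz * uz - par * par, 0.0)
    inside = (par / a) ** 2 + perp2 / b**2 <= 1.0
    if not inside.any():
        raise ValueError("ellipsoid does not intersect the grid")
    return LabelVolume(grid=grid, voxels=inside, role="ablation_pred")


def plan_ellipsoids(
    table: ManufacturerTable,
    plan: list[tuple[ApplicatorPose, AblationSetting]],
) -> list[EllipsoidSpec]:
    """One manufacturer ellipsoid per planned ablation.

    Each ellipsoid is centered at the active-zone midpoint with its long axis
    along the applicator direction and dimensions looked up at the ablation's
    own (power, time) setting.
    """
    specs = []
    for pose, setting in plan:
        length, diameter = lookup_dimensions(table, setting)
        specs.append(
            EllipsoidSpec(
                center=tuple(pose.zone_midpoint),
                long_axis_direction=pose.direction,
                length=length,
                diameter=diameter,
            )
        )
    return specs


def baseline_prediction(
    table: ManufacturerTable,
    plan: list[tuple[ApplicatorPose, AblationSetting]],
    grid: VoxelGrid,
) -> LabelVolume:
    """Union of manufacturer ellipsoids over all planned ablations."""
    voxels = np.zeros(grid.shape, dtype=bool)
    for spec in plan_ellipsoids(table, plan):
        voxels |= ellipsoid_mask(spec, grid).voxels
    return LabelVolume(grid=grid, voxels=voxels, role="ablation_pred")
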