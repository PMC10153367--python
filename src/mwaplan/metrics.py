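"""Per-case ablation performance metrics.

Dice overlap, signed surface (Hausdorff) distances from the predicted to the
ground-truth ablation surface, volume differences, and the vascular fraction
— the fraction of a representative manufacturer ablation ellipsoid occupied
by segmented vessels, a pre-simulation proxy for the heat-sink effect.

Surfaces are mask boundary voxels (6-connectivity); distances are Euclidean
distance-transform values in mm, so they carry a documented half-voxel
discretization bias. Sub-voxel surface meshing is deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .manufacturer import (
    EllipsoidSpec,
    ManufacturerTable,
    ellipsoid_mask,
    plan_ellipsoids,
)
from .volumes import AblationSetting, ApplicatorPose, LabelVolume, VoxelGrid


@dataclass
class SignedDistanceStats:
    min_mm: float
    max_mm: float
    mean_mm: float
    p95_mm: float


@dataclass
class MetricsResult:
    """All per-case performance indicators."""

    dice: float
    hausdorff_mm: float
    signed_distance_stats: SignedDistanceStats | None
    vol_pred_ml: float
    vol_gt_ml: float
    rel_vol_diff: float
    vascular_fraction: float


def _check_same_grid(a: LabelVolume, b: LabelVolume) -> None:
    if a.grid.shape != b.grid.shape or a.grid.spacing != b.grid.spacing:
        raise ValueError("masks must share one grid")


def dice(a: LabelVolume, b: LabelVolume) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    _check_same_grid(a, b)
    na, nb = a.n_true, b.n_true
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def boundary_voxels(mask: LabelVolume) -> np.ndarray:
    """Boundary of a mask: its voxels with a 6-neighbour outside the mask."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask.voxels, structure=structure, border_value=0)
    return mask.voxels & ~eroded


def signed_surface_distances(
    pred: LabelVolume, gt: LabelVolume
) -> tuple[np.ndarray, float, SignedDistanceStats]:
    """Signed distance (mm) from each predicted-surface voxel to the GT surface.

    Positive where the predicted boundary lies outside the ground truth (the
    ground truth locally enclosed by the prediction), negative where the
    ground truth extends outside the prediction. Returns the distance sample,
    the Hausdorff distance max |d|, and summary statistics.
    """
    _check_same_grid(pred, gt)
    if pred.n_true == 0 or gt.n_true == 0:
        raise ValueError("signed surface distances require nonempty masks")
    pred_surf = boundary_voxels(pred)
    gt_surf = boundary_voxels(gt)
    dist_to_gt_surface = ndimage.distance_transform_edt(
        ~gt_surf, sampling=pred.grid.spacing
    )
    d = dist_to_gt_surface[pred_surf]
    sign = np.where(gt.voxels[pred_surf], -1.0, 1.0)
    signed = sign * d
    stats = SignedDistanceStats(
        min_mm=float(signed.min()),
        max_mm=float(signed.max()),
        mean_mm=float(signed.mean()),
        p95_mm=float(np.percentile(signed, 95)),
    )
    hausdorff = float(np.abs(signed).max())
    return signed, hausdorff, stats


def vascular_fraction(
    vessels: LabelVolume, ellipsoid: EllipsoidSpec, grid: VoxelGrid
) -> float:
    """|vessels n ellipsoid| / |ellipsoid| on the given grid."""
    emask = ellipsoid_mask(ellipsoid, grid)
    n = emask.n_true
    inter = int(np.logical_and(vessels.voxels, emask.voxels).sum())
    return inter / n


def evaluate_case(
    pred: LabelVolume,
    gt: LabelVolume,
    vessels: LabelVolume | None = None,
    table: ManufacturerTable | None = None,
    plan: list[tuple[ApplicatorPose, AblationSetting]] | None = None,
) -> MetricsResult:
    """Populate every metric for one case.

    The vascular fraction uses the manufacturer's representative ellipsoid at
    each planned ablation's own setting, taking the maximum over sequential
    ablations (the most vessel-affected ablation governs the cooling risk);
    it is 0 when vessels, table or plan are not supplied.
    """
    _check_same_grid(pred, gt)
    d = dice(pred, gt)
    if pred.n_true and gt.n_true:
        _, hausdorff, stats = signed_surface_distances(pred, gt)
    else:
        hausdorff, stats = float("nan"), None
    vol_pred, vol_gt = pred.volume_ml, gt.volume_ml
    rel_vol_diff = abs(vol_pred - vol_gt) / vol_gt if vol_gt > 0 else float("nan")
    vf = 0.0
    if vessels is not None and table is not None and plan:
        vf = max(
            vascular_fraction(vessels, spec, pred.grid)
            for spec in plan_ellipsoids(table, plan)
        )
    return MetricsResult(
        dice=d,
        hausdorff_mm=hausdorff,
        signed_distance_stats=stats,
        vol_pred_ml=vol_pred,
        vol_gt_ml=vol_gt,
        rel_vol_diff=rel_vol_diff,
        vascular_fraction=vf,
    )
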