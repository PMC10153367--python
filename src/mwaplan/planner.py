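"""Plan-level simulation: run each ablation of a plan and unite the results.

Each ablation of a plan is simulated independently from a fresh body-
temperature initial field (sequential ablations are treated as independent)
on a local subdomain around its active zone — the full ablation fits well
inside a few-centimetre neighbourhood, so restricting the implicit solve to
that box (with the Dirichlet body-temperature boundary on its faces) changes
the result negligibly while keeping multi-ablation cohorts fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants
from .bioheat import SimulationResult, SolverConfig, TissueProperties, simulate
from .damage import DamageField, ablation_mask, union_sequential
from .source import ApplicatorSource, SourceModel
from .volumes import AblationSetting, ApplicatorPose, LabelVolume, VoxelGrid

Plan = list[tuple[ApplicatorPose, AblationSetting]]


@dataclass(frozen=True)
class PlanConfig:
    """Configuration of plan-level simulation."""

    solver: SolverConfig = field(default_factory=lambda: SolverConfig(dt=5.0))
    subdomain_margin_mm: float = 30.0
    omega_threshold: float = constants.OMEGA_THRESHOLD
    vascular_cooling: bool = True   # apply the elevated vessel-subdomain sink
    # carry residual tissue heating from one ablation into the next instead of
    # restarting from body temperature (sequential ablations independent)
    warm_start: bool = False


def active_zone_bounds(
    pose: ApplicatorPose, grid: VoxelGrid, margin_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel index range (lo, hi) of the active zone expanded by a margin."""
    pts = np.vstack([np.asarray(pose.tip), pose.zone_end])
    lo_w = pts.min(axis=0) - margin_mm
    hi_w = pts.max(axis=0) + margin_mm
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    lo = np.maximum(np.floor((lo_w - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((hi_w - origin) / spacing).astype(int) + 1, grid.shape)
    if np.any(hi <= lo):
        raise ValueError("active zone (plus margin) does not intersect the grid")
    return lo, hi


@dataclass
class AblationOutcome:
    mask: LabelVolume               # on the full grid
    damage: DamageField             # on the full grid
    subgrid: VoxelGrid
    result: SimulationResult        # on the subgrid


def simulate_ablation(
    grid: VoxelGrid,
    pose: ApplicatorPose,
    setting: AblationSetting,
    model: SourceModel,
    props: TissueProperties,
    config: PlanConfig = PlanConfig(),
    vessel_mask: np.ndarray | LabelVolume | None = None,
    initial_temperature: np.ndarray | None = None,
) -> AblationOutcome:
    """Simulate one ablation on its local subdomain; embed results on the grid.

    ``initial_temperature``, if given, is a full-grid field from which the
    subdomain's initial condition is sliced (warm-start chaining).
    """
    if isinstance(vessel_mask, LabelVolume):
        vessel_mask = vessel_mask.voxels
    lo, hi = active_zone_bounds(pose, grid, config.subdomain_margin_mm)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    subgrid = grid.subgrid(lo, hi)
    sub_vessels = None
    if vessel_mask is not None and config.vascular_cooling:
        sub_vessels = np.asarray(vessel_mask, dtype=bool)[sl]
    source = ApplicatorSource(model, pose, subgrid, setting.power)
    initial = None
    if initial_temperature is not None:
        from .bioheat import TemperatureField

        initial = TemperatureField(grid=subgrid, values=initial_temperature[sl].copy())
    result = simulate(
        subgrid, setting.duration, props, source, config.solver,
        vessel_mask=sub_vessels, initial=initial,
    )
    omega_full = np.zeros(grid.shape)
    omega_full[sl] = result.damage_omega
    damage = DamageField(grid=grid, omega=omega_full)
    mask, _ = ablation_mask(damage, config.omega_threshold)
    return AblationOutcome(mask=mask, damage=damage, subgrid=subgrid, result=result)


@dataclass
class PlanResult:
    outcomes: list[AblationOutcome]
    union_mask: LabelVolume

    @property
    def volume_ml(self) -> float:
        return self.union_mask.volume_ml


def run_plan(
    grid: VoxelGrid,
    plan: Plan,
    model: SourceModel,
    props: TissueProperties,
    config: PlanConfig = PlanConfig(),
    vessel_mask: np.ndarray | LabelVolume | None = None,
) -> PlanResult:
    """Simulate every ablation of a plan and unite the predicted masks.

    By default each ablation restarts from a uniform body-temperature field
    (sequential ablations independent). With ``config.warm_start`` the final
    temperature of each ablation seeds the next one's initial condition.
    """
    if not plan:
        raise ValueError("empty ablation plan")
    outcomes = []
    carry: np.ndarray | None = None
    for pose, setting in plan:
        outcome = simulate_ablation(
            grid, pose, setting, model, props, config, vessel_mask,
            initial_temperature=carry,
        )
        outcomes.append(outcome)
        if config.warm_start:
            if carry is None:
                carry = np.full(grid.shape, props.t_b)
            lo, hi = active_zone_bounds(pose, grid, config.subdomain_margin_mm)
            sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
            carry[sl] = outcome.result.final.values
    union = union_sequential([o.mask for o in outcomes])
    return PlanResult(outcomes=outcomes, union_mask=union)
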