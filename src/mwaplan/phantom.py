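"""Synthetic liver/vessel/ablation phantoms.

Generates complete desk-scale cases emulating the structure of a clinical
MWA cohort: an ellipsoidal liver with a smoothly perturbed surface, a
seeded branching vessel tree (tapered tubes, radii >= 1 mm — thinner
branches do not produce a relevant heat sink), applicator plans drawn from
the clinically observed ranges (80/90/100 W, 3-10 min, 1-6 sequential
ablations), and a synthetic "ground truth" ablation.

The ground truth is generated BY the biophysical model itself (with vascular
cooling), optionally degraded by two controlled artifacts observed in real
retrospective data: a rigid misalignment of the ground truth relative to the
applicator (emulating scan-to-scan registration error) and a wedge-shaped
inflation towards the liver edge (emulating vasculature-shortage infarction,
which images like ablated tissue). Because the ground truth comes from the
model, closed-loop metrics exercise the *pipeline* with known answers; they
are not a clinical validation.

All sampling flows from one seeded generator per case; a fixed (seed, spec)
pair reproduces every mask bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import ndimage

from . import constants
from .bioheat import TissueProperties
from .manufacturer import ManufacturerTable
from .planner import Plan, PlanConfig, run_plan
from .source import SourceModel
from .volumes import AblationSetting, ApplicatorPose, LabelVolume, VoxelGrid


@dataclass(frozen=True)
class VesselTreeSpec:
    n_roots: int = 2
    levels: int = 3                      # branching generations below the root
    root_radius_mm: float = 4.0
    radius_decay: float = 0.7            # per branching level
    min_radius_mm: float = 1.0           # thinner branches are not generated
    segment_length_mm: tuple[float, float] = (18.0, 30.0)
    branch_angle_deg: tuple[float, float] = (20.0, 50.0)

    def __post_init__(self):
        if self.min_radius_mm < 1.0:
            raise ValueError("min_radius_mm must be >= 1 mm")
        if not (0 < self.radius_decay < 1):
            raise ValueError("radius_decay must lie in (0, 1)")


@dataclass(frozen=True)
class PlanSamplerSpec:
    powers_w: tuple[float, ...] = (80.0, 90.0, 100.0)
    # durations are whole minutes, as clinically programmed
    duration_min_range: tuple[float, float] = (3.0, 10.0)
    n_ablations_range: tuple[int, int] = (1, 6)
    tip_scatter_mm: float = 8.0          # lateral offset between sequential ablations

    def __post_init__(self):
        lo, hi = self.n_ablations_range
        if not (1 <= lo <= hi <= 6):
            raise ValueError("n_ablations_range must lie within [1, 6]")

    def sample_settings(
        self, rng: np.random.Generator, n_ablations: int | None = None
    ) -> list[AblationSetting]:
        if n_ablations is None:
            n_ablations = int(rng.integers(self.n_ablations_range[0],
                                           self.n_ablations_range[1] + 1))
        lo, hi = self.duration_min_range
        return [
            AblationSetting.from_minutes(
                float(rng.choice(self.powers_w)),
                float(rng.integers(int(np.ceil(lo)), int(np.floor(hi)) + 1)),
            )
            for _ in range(n_ablations)
        ]


@dataclass(frozen=True)
class ArtifactSpec:
    misalignment_mm: float = 0.0         # rigid ground-truth shift magnitude
    shortage_inflation: bool = False     # wedge towards the liver edge
    wedge_half_angle_deg: float = 20.0


@dataclass(frozen=True)
class PhantomSpec:
    grid: VoxelGrid = field(default_factory=lambda: VoxelGrid(shape=(128, 128, 128)))
    liver_semiaxes_mm: tuple[float, float, float] = (52.0, 42.0, 36.0)
    surface_perturbation: float = 0.03   # relative radial amplitude
    perturbation_smoothness_mm: float = 12.0
    vessels: VesselTreeSpec = field(default_factory=VesselTreeSpec)
    plans: PlanSamplerSpec = field(default_factory=PlanSamplerSpec)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)

    def replace(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)


def generate_liver(spec: PhantomSpec, rng: np.random.Generator) -> LabelVolume:
    """Ellipsoidal liver mask with a smooth seeded surface perturbation."""
    grid = spec.grid
    half_extent = np.asarray(grid.shape) * np.asarray(grid.spacing) / 2.0
    if np.any(np.asarray(spec.liver_semiaxes_mm) >= half_extent):
        raise ValueError("liver semi-axes exceed the grid")
    c = grid.center()
    x, y, z = grid.coordinate_arrays()
    a1, a2, a3 = spec.liver_semiaxes_mm
    r = np.sqrt(((x - c[0]) / a1) ** 2 + ((y - c[1]) / a2) ** 2 + ((z - c[2]) / a3) ** 2)
    if spec.surface_perturbation > 0:
        noise = rng.standard_normal(grid.shape)
        sigma_vox = spec.perturbation_smoothness_mm / np.asarray(grid.spacing)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        smooth /= max(smooth.std(), 1e-12)
        r = r / (1.0 + spec.surface_perturbation * smooth)
    return LabelVolume(grid=grid, voxels=r <= 1.0, role="liver")


def _rasterize_tube(
    voxels: np.ndarray, grid: VoxelGrid, a: np.ndarray, b: np.ndarray, radius: float
) -> None:
    """OR a capsule of given radius around segment [a, b] into ``voxels``."""
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    lo_w = np.minimum(a, b) - radius - spacing
    hi_w = np.maximum(a, b) + radius + spacing
    lo = np.clip(np.floor((lo_w - origin) / spacing).astype(int), 0, grid.shape)
    hi = np.clip(np.ceil((hi_w - origin) / spacing).astype(int) + 1, 0, grid.shape)
    if np.any(hi <= lo):
        return
    sub = grid.subgrid(lo, hi)
    from .volumes import segment_distance

    d = segment_distance(sub, a, b)
    sl = tuple(slice(int(p), int(q)) for p, q in zip(lo, hi))
    voxels[sl] |= d <= radius


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _rotate_towards(direction: np.ndarray, angle_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Unit vector at the given angle from ``direction``, random azimuth."""
    d = direction / np.linalg.norm(direction)
    perp = np.cross(d, _random_direction(rng))
    n = np.linalg.norm(perp)
    while n < 1e-8:
        perp = np.cross(d, _random_direction(rng))
        n = np.linalg.norm(perp)
    perp /= n
    out = np.cos(angle_rad) * d + np.sin(angle_rad) * perp
    return out / np.linalg.norm(out)


def generate_vessel_tree(
    spec: PhantomSpec, liver: LabelVolume, rng: np.random.Generator
) -> tuple[LabelVolume, nx.DiGraph]:
    """Seeded recursive branching of tapered tubes inside the liver.

    Returns the rasterized vessel mask (clipped to the liver) and a directed
    centerline graph whose nodes carry ``pos`` (mm) and ``radius`` (mm) and
    whose edges record parent -> child topology.
    """
    if liver.n_true == 0:
        raise ValueError("liver mask is empty")
    vspec = spec.vessels
    grid = spec.grid
    center = grid.center()
    voxels = np.zeros(grid.shape, dtype=bool)
    graph = nx.DiGraph()
    node_counter = [0]

    # roots start inside the liver, offset from center, heading across it
    idx = np.argwhere(liver.voxels)
    extent = np.asarray(spec.liver_semiaxes_mm)

    def _add_node(pos: np.ndarray, radius: float, level: int) -> int:
        nid = node_counter[0]
        node_counter[0] += 1
        graph.add_node(nid, pos=tuple(float(p) for p in pos), radius=float(radius), level=level)
        return nid

    def _grow(parent_id: int, pos: np.ndarray, direction: np.ndarray, radius: float, level: int):
        if level > vspec.levels or radius < vspec.min_radius_mm:
            return
        length = rng.uniform(*vspec.segment_length_mm)
        end = pos + direction * length
        # keep endpoints loosely inside the liver envelope
        rel = (end - center) / extent
        if np.linalg.norm(rel) > 0.92:
            end = pos + direction * (length * 0.4)
        _rasterize_tube(voxels, grid, pos, end, radius)
        nid = _add_node(end, radius, level)
        graph.add_edge(parent_id, nid)
        child_radius = radius * vspec.radius_decay
        if child_radius < vspec.min_radius_mm:
            return
        for _ in range(2):
            angle = np.deg2rad(rng.uniform(*vspec.branch_angle_deg))
            child_dir = _rotate_towards(direction, angle, rng)
            _grow(nid, end, child_dir, child_radius, level + 1)

    for _ in range(vspec.n_roots):
        start_rel = _random_direction(rng) * 0.75
        start = center + start_rel * extent
        direction = (center - start) + _random_direction(rng) * 10.0
        direction /= np.linalg.norm(direction)
        root_id = _add_node(start, vspec.root_radius_mm, 0)
        _grow(root_id, start, direction, vspec.root_radius_mm, 1)

    voxels &= liver.voxels
    return LabelVolume(grid=grid, voxels=voxels, role="vessel"), graph


def sample_plan(
    spec: PhantomSpec,
    target: np.ndarray,
    rng: np.random.Generator,
    n_ablations: int | None = None,
    settings: list[AblationSetting] | None = None,
) -> Plan:
    """Applicator plan around a target point.

    Settings (power/duration per ablation) are sampled from the spec unless a
    pre-drawn list is supplied (used by the cohort generator to pair settings
    across vascular-fraction groups).
    """
    pspec = spec.plans
    if settings is None:
        settings = pspec.sample_settings(rng, n_ablations)
    direction = _random_direction(rng)
    plan: Plan = []
    for i, setting in enumerate(settings):
        offset = np.zeros(3)
        if i > 0:
            perp = np.cross(direction, _random_direction(rng))
            perp /= max(np.linalg.norm(perp), 1e-8)
            offset = perp * rng.uniform(0.4, 1.0) * pspec.tip_scatter_mm
        # tip placed so the active-zone midpoint sits on the (offset) target
        pose = ApplicatorPose(
            tip=tuple(target + offset + direction * (constants.ACTIVE_ZONE_LENGTH_MM / 2.0)),
            direction=tuple(direction),
        )
        plan.append((pose, setting))
    return plan


def _select_target(
    liver: LabelVolume,
    vessels: LabelVolume,
    rng: np.random.Generator,
    near_vessel: bool,
    near_range_mm: tuple[float, float] = (1.0, 4.0),
    far_min_mm: float = 25.0,
    liver_margin_mm: float = 12.0,
) -> np.ndarray:
    """Target point inside the liver, constructively near or far from vessels."""
    grid = liver.grid
    interior = ndimage.binary_erosion(
        liver.voxels, iterations=int(round(liver_margin_mm / min(grid.spacing)))
    )
    vessel_dist = ndimage.distance_transform_edt(~vessels.voxels, sampling=grid.spacing)
    if near_vessel:
        candidates = interior & (vessel_dist >= near_range_mm[0]) & (vessel_dist <= near_range_mm[1])
    else:
        candidates = interior & (vessel_dist >= far_min_mm)
    if not candidates.any():
        # relax: farthest/nearest admissible interior point
        masked = np.where(interior, vessel_dist, np.inf if near_vessel else -np.inf)
        pick = np.unravel_index(
            np.argmin(masked) if near_vessel else np.argmax(masked), grid.shape
        )
        return grid.index_to_world(np.asarray(pick))
    idx = np.argwhere(candidates)
    pick = idx[rng.integers(len(idx))]
    return grid.index_to_world(pick)


@dataclass
class PhantomCase:
    """One complete synthetic case."""

    case_id: str
    seed: int
    grid: VoxelGrid
    liver: LabelVolume
    vessels: LabelVolume
    vessel_graph: nx.DiGraph
    plan: Plan
    ground_truth: LabelVolume
    model_prediction: LabelVolume        # cooling-on prediction used to build GT
    overestimated_gt: bool = False
    misaligned_applicator: bool = False
    target_high_vf: bool = False


def _apply_misalignment(
    gt: LabelVolume, magnitude_mm: float, rng: np.random.Generator
) -> LabelVolume:
    direction = _random_direction(rng)
    shift_vox = np.round(direction * magnitude_mm / np.asarray(gt.grid.spacing)).astype(int)
    if not shift_vox.any():
        shift_vox[int(np.argmax(np.abs(direction)))] = max(
            1, int(round(magnitude_mm / max(gt.grid.spacing)))
        )
    shifted = ndimage.shift(gt.voxels.astype(np.uint8), shift_vox, order=0, cval=0)
    return gt.with_voxels(shifted.astype(bool))


def _apply_shortage_wedge(
    gt: LabelVolume, liver: LabelVolume, half_angle_deg: float
) -> LabelVolume:
    """Inflate the ground truth by an infarct cone towards the liver edge.

    The cone apex sits at the ablation centroid. Among a fixed set of
    candidate directions (towards the nearest capsule point, away from the
    liver center, and the six axis directions) the one adding the most
    liver tissue beyond the existing ablation is kept, so the artifact
    reliably overestimates the ground truth volume.
    """
    grid = gt.grid
    centroid = grid.index_to_world(np.argwhere(gt.voxels).mean(axis=0))
    _, nearest = ndimage.distance_transform_edt(
        liver.voxels, sampling=grid.spacing, return_indices=True
    )
    cvox = np.round((centroid - np.asarray(grid.origin)) / np.asarray(grid.spacing)).astype(int)
    cvox = np.clip(cvox, 0, np.asarray(grid.shape) - 1)
    edge_idx = nearest[:, cvox[0], cvox[1], cvox[2]]
    liver_centroid = grid.index_to_world(np.argwhere(liver.voxels).mean(axis=0))
    candidates = [
        grid.index_to_world(edge_idx) - centroid,
        centroid - liver_centroid,
        np.array([1.0, 0, 0]), np.array([-1.0, 0, 0]),
        np.array([0, 1.0, 0]), np.array([0, -1.0, 0]),
        np.array([0, 0, 1.0]), np.array([0, 0, -1.0]),
    ]
    x, y, z = grid.coordinate_arrays()
    dx, dy, dz = x - centroid[0], y - centroid[1], z - centroid[2]
    dist = np.sqrt(dx * dx + dy * dy + dz * dz)
    cos_half = np.cos(np.deg2rad(half_angle_deg))
    best_wedge, best_added = None, -1
    for u in candidates:
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            continue
        u = u / norm
        proj = dx * u[0] + dy * u[1] + dz * u[2]
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(dist > 0, proj / dist, 1.0)
        wedge = (proj > 0) & (cos >= cos_half) & liver.voxels
        added = int((wedge & ~gt.voxels).sum())
        if added > best_added:
            best_wedge, best_added = wedge, added
    return gt.with_voxels(gt.voxels | best_wedge)


def generate_case(
    spec: PhantomSpec,
    model: SourceModel,
    table: ManufacturerTable,
    props: TissueProperties,
    seed: int,
    case_id: str = "case",
    plan_config: PlanConfig = PlanConfig(),
    high_vf: bool = False,
    n_ablations: int | None = None,
    settings: list[AblationSetting] | None = None,
) -> PhantomCase:
    """Generate one full synthetic case (see module docstring).

    The ground truth is the model's own cooling-on prediction, then degraded
    by the artifacts configured in ``spec.artifacts``; artifact labels are
    stored as the case's exclusion flags.
    """
    rng = np.random.default_rng(seed)
    liver = generate_liver(spec, rng)
    vessels, graph = generate_vessel_tree(spec, liver, rng)
    target = _select_target(liver, vessels, rng, near_vessel=high_vf)
    plan = sample_plan(spec, target, rng, n_ablations=n_ablations, settings=settings)
    result = run_plan(
        spec.grid, plan, model, props, plan_config, vessel_mask=vessels.voxels
    )
    prediction = result.union_mask
    gt = prediction.with_voxels(prediction.voxels.copy())
    gt.role = "ablation_gt"
    misaligned = spec.artifacts.misalignment_mm > 0
    overestimated = spec.artifacts.shortage_inflation
    if misaligned:
        gt = _apply_misalignment(gt, spec.artifacts.misalignment_mm, rng)
    if overestimated:
        gt = _apply_shortage_wedge(gt, liver, spec.artifacts.wedge_half_angle_deg)
    return PhantomCase(
        case_id=case_id,
        seed=seed,
        grid=spec.grid,
        liver=liver,
        vessels=vessels,
        vessel_graph=graph,
        plan=plan,
        ground_truth=gt,
        model_prediction=prediction,
        overestimated_gt=overestimated,
        misaligned_applicator=misaligned,
        target_high_vf=high_vf,
    )


def generate_cohort(
    n_cases: int,
    master_seed: int,
    spec: PhantomSpec,
    model: SourceModel,
    table: ManufacturerTable,
    props: TissueProperties,
    plan_config: PlanConfig = PlanConfig(),
    high_vf_fraction: float = 0.5,
    misalignment_rate: float = 0.0,
    shortage_rate: float = 0.0,
    misalignment_mm: float = 5.0,
    n_ablations: int | None = None,
) -> list[PhantomCase]:
    """Reproducible cohort with a controlled vascular-fraction spread.

    Roughly ``high_vf_fraction`` of the cases place the applicator adjacent
    to a root vessel (high VF); the rest keep vessels far away. Plan
    settings are drawn once per case *slot* and shared between the high-VF
    case and its low-VF counterpart, so the two groups see the same
    power/duration mix and differ only in vascular geometry. Artifact rates
    plant misalignment/shortage labels on a seeded subset.
    """
    if n_cases < 4:
        raise ValueError("a cohort needs at least 4 cases")
    seeds = np.random.SeedSequence(master_seed).generate_state(2 * n_cases)
    assign_rng = np.random.default_rng(seeds[0])
    cases = []
    n_high = int(round(high_vf_fraction * n_cases))
    n_slots = max(n_high, n_cases - n_high)
    schedules = [
        spec.plans.sample_settings(assign_rng, n_ablations) for _ in range(n_slots)
    ]
    for i in range(n_cases):
        high = i < n_high
        slot = i if high else i - n_high
        case_seed = int(seeds[n_cases + i] % (2**31 - 1))
        artifacts = ArtifactSpec(
            misalignment_mm=(
                misalignment_mm if assign_rng.random() < misalignment_rate else 0.0
            ),
            shortage_inflation=bool(assign_rng.random() < shortage_rate),
        )
        cases.append(
            generate_case(
                spec.replace(artifacts=artifacts),
                model,
                table,
                props,
                seed=case_seed,
                case_id=f"C{i + 1:03d}",
                plan_config=plan_config,
                high_vf=high,
                settings=schedules[slot % n_slots],
            )
        )
    return cases
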