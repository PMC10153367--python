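"""End-to-end orchestration: calibrate -> phantom -> simulate -> evaluate -> stats.

Thin wiring over the library modules with a YAML config, per-stage timing and
a provenance manifest. Each stage writes into its own subdirectory of the
output folder and never mutates another stage's outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, constants
from .bioheat import TissueProperties
from .cohort import aggregate, identity_rel_distance, make_cohort_table
from .manufacturer import ManufacturerTable, baseline_prediction, load_default_table
from .metrics import evaluate_case
from .phantom import PhantomCase, PhantomSpec, generate_cohort
from .planner import PlanConfig, run_plan
from .source import CalibrationConfig, SourceModel, calibrate
from .volumes import VoxelGrid, write_mask


def evaluate_cohort(
    cases: list[PhantomCase],
    model: SourceModel,
    table: ManufacturerTable,
    props: TissueProperties,
    plan_config: PlanConfig = PlanConfig(),
    rerun_model: bool = False,
) -> pd.DataFrame:
    """Per-case metrics for model and manufacturer-baseline predictions.

    By default the model prediction stored in each case (generated with the
    same plan configuration) is reused; ``rerun_model`` forces a fresh
    simulation, e.g. with a different ``plan_config`` (cooling disabled).
    """
    rows = []
    for case in cases:
        if rerun_model:
            pred = run_plan(
                case.grid, case.plan, model, props, plan_config,
                vessel_mask=case.vessels.voxels,
            ).union_mask
        else:
            pred = case.model_prediction
        baseline = baseline_prediction(table, case.plan, case.grid)
        m_model = evaluate_case(pred, case.ground_truth, case.vessels, table, case.plan)
        m_manu = evaluate_case(baseline, case.ground_truth, case.vessels, table, case.plan)
        rows.append(
            {
                "case_id": case.case_id,
                "vol_model_ml": m_model.vol_pred_ml,
                "vol_manufacturer_ml": m_manu.vol_pred_ml,
                "vol_gt_ml": m_model.vol_gt_ml,
                "dice_model": m_model.dice,
                "dice_manufacturer": m_manu.dice,
                "hausdorff_model": m_model.hausdorff_mm,
                "hausdorff_manufacturer": m_manu.hausdorff_mm,
                "rel_vol_diff_model": m_model.rel_vol_diff,
                "rel_vol_diff_manufacturer": m_manu.rel_vol_diff,
                "vascular_fraction": m_model.vascular_fraction,
                "overestimated_gt": case.overestimated_gt,
                "misaligned_applicator": case.misaligned_applicator,
            }
        )
    return make_cohort_table(rows)


@dataclass
class StageRecord:
    name: str
    seconds: float
    outputs: list[str] = field(default_factory=list)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[StageRecord] = field(default_factory=list)

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2))


class ConfigError(ValueError):
    """Pipeline configuration schema violation."""


_DEFAULT_CONFIG = {
    "seed": 0,
    "n_cases": 4,
    "grid_shape": [96, 96, 96],
    "grid_spacing_mm": 1.0,
    "n_ablations": None,
    "table": None,                 # path to CSV; None -> bundled synthetic table
    "source_model": None,          # path to YAML; None -> calibrate from template
    "calibrate": False,
    "dt_s": 5.0,
    "high_vf_fraction": 0.5,
    "misalignment_rate": 0.0,
    "shortage_rate": 0.0,
    "liver_semiaxes_mm": None,
    "vf_threshold_candidates": [0.01, 0.03, 0.05, 0.08, 0.12],
    "write_masks": False,
}


def load_config(path: str | Path) -> dict:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("pipeline config must be a YAML mapping")
    unknown = set(raw) - set(_DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    cfg = {**_DEFAULT_CONFIG, **raw}
    if cfg["table"] is not None and not Path(cfg["table"]).exists():
        raise ConfigError(f"table file not found: {cfg['table']}")
    if cfg["source_model"] is None and not cfg["calibrate"]:
        raise ConfigError("config must set 'source_model' (path) or 'calibrate: true'")
    return cfg


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> RunManifest:
    """Execute the configured stages in order, fail-fast, with a manifest."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()[:16]
    manifest = RunManifest(config_hash=config_hash, seed=int(cfg["seed"]), version=__version__)
    props = TissueProperties()

    def stage(name):
        t0 = time.perf_counter()

        def done(outputs=()):
            manifest.stages.append(
                StageRecord(name=name, seconds=time.perf_counter() - t0,
                            outputs=[str(o) for o in outputs])
            )

        return done

    # -- table -------------------------------------------------------------
    done = stage("table")
    table = (
        ManufacturerTable.from_csv(cfg["table"]) if cfg["table"] else load_default_table()
    )
    done()

    # -- source model ------------------------------------------------------
    done = stage("source_model")
    if cfg["source_model"]:
        model = SourceModel.from_yaml(cfg["source_model"])
        done([cfg["source_model"]])
    else:
        result = calibrate(SourceModel(), table, props, CalibrationConfig())
        model_path = out / "source_model.yaml"
        result.model.to_yaml(model_path)
        model = result.model
        done([model_path])

    # -- phantom cohort (includes the model's cooling-on simulations) ------
    done = stage("phantom")
    grid = VoxelGrid(
        shape=tuple(cfg["grid_shape"]),
        spacing=(cfg["grid_spacing_mm"],) * 3,
    )
    spec = PhantomSpec(grid=grid)
    if cfg["liver_semiaxes_mm"]:
        spec = spec.replace(liver_semiaxes_mm=tuple(cfg["liver_semiaxes_mm"]))
    plan_config = PlanConfig()
    plan_config = PlanConfig(solver=plan_config.solver.__class__(dt=float(cfg["dt_s"])))
    cases = generate_cohort(
        n_cases=int(cfg["n_cases"]),
        master_seed=int(cfg["seed"]),
        spec=spec,
        model=model,
        table=table,
        props=props,
        plan_config=plan_config,
        high_vf_fraction=float(cfg["high_vf_fraction"]),
        misalignment_rate=float(cfg["misalignment_rate"]),
        shortage_rate=float(cfg["shortage_rate"]),
        n_ablations=cfg["n_ablations"],
    )
    outputs = []
    if cfg["write_masks"]:
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        for case in cases:
            for name, vol in (
                ("liver", case.liver), ("vessels", case.vessels),
                ("gt", case.ground_truth), ("pred", case.model_prediction),
            ):
                p = mask_dir / f"{case.case_id}_{name}.nii.gz"
                write_mask(vol, p)
                outputs.append(p)
    done(outputs)

    # -- evaluation --------------------------------------------------------
    done = stage("evaluate")
    cohort_df = evaluate_cohort(cases, model, table, props, plan_config)
    cohort_csv = out / "cohort.csv"
    cohort_df.to_csv(cohort_csv, index=False)
    done([cohort_csv])

    # -- cohort statistics -------------------------------------------------
    done = stage("cohort_stats")
    summary = aggregate(cohort_df, apply_exclusions=False)
    idd = identity_rel_distance(
        cohort_df["vol_manufacturer_ml"].to_numpy(),
        cohort_df["vol_model_ml"].to_numpy(),
    )
    report = {
        "n_cases": int(len(cohort_df)),
        "pearson_r_volumes": summary.pearson_r_volumes,
        "delta_rel_vol_diff": summary.delta_rel_vol_diff,
        "delta_hausdorff_mm": summary.delta_hausdorff_mm,
        "delta_dice": summary.delta_dice,
        "identity_rel_distance_mean": float(np.mean(idd)),
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    done([report_path])

    manifest.to_json(out / "manifest.json")
    return manifest
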