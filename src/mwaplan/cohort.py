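"""Cohort-level statistical reporting.

Reproduces the study-style analysis layer: per-case relative distance from
the identity line between model-predicted and manufacturer-predicted
volumes, a two-group Tukey (studentized-range) 95% confidence-interval test
split on vascular fraction, a scan for the vascular-fraction threshold at
which the cooling effect becomes significant, and box-and-whisker aggregates
of the performance indicators with expert-review exclusion flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

COHORT_COLUMNS = [
    "case_id",
    "vol_model_ml",
    "vol_manufacturer_ml",
    "vol_gt_ml",
    "dice_model",
    "dice_manufacturer",
    "hausdorff_model",
    "hausdorff_manufacturer",
    "rel_vol_diff_model",
    "rel_vol_diff_manufacturer",
    "vascular_fraction",
    "overestimated_gt",
    "misaligned_applicator",
]


def make_cohort_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble and validate a per-case cohort table."""
    df = pd.DataFrame(rows)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    df = df[COHORT_COLUMNS]
    vf = df["vascular_fraction"]
    if ((vf < 0) | (vf > 1)).any():
        raise ValueError("vascular_fraction must lie in [0, 1]")
    for col in ("vol_model_ml", "vol_manufacturer_ml"):
        if (df[col] <= 0).any():
            raise ValueError(f"{col} must be > 0 for simulated cases")
    return df


def identity_rel_distance(x: float | np.ndarray, y: float | np.ndarray) -> np.ndarray | float:
    """Relative distance (y - x) / x of a point from the identity line y = x."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("reference volumes must be > 0")
    return (np.asarray(y, dtype=float) - x) / x


@dataclass
class TukeyResult:
    """Two-group studentized-range 95% confidence interval."""

    mean_a: float
    mean_b: float
    mean_difference: float      # mean_a - mean_b
    ci_low: float
    ci_high: float
    significant: bool
    n_a: int
    n_b: int

    def __post_init__(self):
        if not (self.ci_low <= self.mean_difference <= self.ci_high):
            raise ValueError("CI must bracket the mean difference")


def tukey_groups(
    group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05
) -> TukeyResult:
    """Tukey (studentized-range) CI for the difference of two group means.

    Uses the Tukey–Kramer half-width q * sqrt(MSW/2 * (1/n_a + 1/n_b)) with
    the pooled within-group variance; significant iff the CI excludes 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    df_w = n_a + n_b - 2
    ssw = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    msw = ssw / df_w
    q_crit = sps.studentized_range.ppf(1 - alpha, 2, df_w)
    half = q_crit * np.sqrt(msw / 2.0 * (1.0 / n_a + 1.0 / n_b))
    diff = float(a.mean() - b.mean())
    lo, hi = diff - half, diff + half
    return TukeyResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_difference=diff,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0 or hi < 0),
        n_a=n_a,
        n_b=n_b,
    )


def split_by_vascular_fraction(
    table: pd.DataFrame, threshold: float, column: str
) -> tuple[np.ndarray, np.ndarray]:
    """Values of ``column`` for the high-VF group (> threshold) and the rest."""
    high = table["vascular_fraction"] > threshold
    return table.loc[high, column].to_numpy(), table.loc[~high, column].to_numpy()


def vf_threshold_scan(
    table: pd.DataFrame,
    values: np.ndarray,
    candidates: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float | None, dict[float, TukeyResult]]:
    """Smallest candidate VF threshold with a significant Tukey split.

    ``values`` are the per-case statistics to compare (e.g. |identity-line
    distance|), aligned with the rows of ``table``. Candidates that leave
    fewer than two cases on either side are skipped; if none is valid an
    error is raised, and if no valid candidate is significant the returned
    threshold is None.
    """
    values = np.asarray(values, dtype=float)
    vf = table["vascular_fraction"].to_numpy()
    results: dict[float, TukeyResult] = {}
    found: float | None = None
    for thr in sorted(candidates):
        high = vf > thr
        if high.sum() < 2 or (~high).sum() < 2:
            continue
        res = tukey_groups(values[high], values[~high], alpha=alpha)
        results[float(thr)] = res
        if res.significant and found is None:
            found = float(thr)
    if not results:
        raise ValueError("no candidate threshold yields two valid groups")
    return found, results


@dataclass
class WhiskerSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "WhiskerSummary":
        v = np.asarray(values, dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        in_lo = v[v >= q1 - 1.5 * iqr]
        in_hi = v[v <= q3 + 1.5 * iqr]
        return cls(
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            whisker_low=float(in_lo.min()),
            whisker_high=float(in_hi.max()),
        )


@dataclass
class CohortSummary:
    n_included: int
    n_excluded: int
    whiskers: dict[str, dict[str, WhiskerSummary]]  # indicator -> {model, manufacturer}
    pearson_r_volumes: float | None
    # paired mean deltas, oriented so that positive favours the model
    delta_rel_vol_diff: float
    delta_hausdorff_mm: float
    delta_dice: float


def aggregate(table: pd.DataFrame, apply_exclusions: bool = False) -> CohortSummary:
    """Box-and-whisker aggregates and paired model-vs-manufacturer deltas.

    Whiskers use the Tukey 1.5*IQR convention. ``apply_exclusions`` drops
    cases flagged by expert review (overestimated ground truth, misaligned
    applicator). The Pearson correlation is computed on untransformed model
    vs manufacturer volumes and reported as None when degenerate.
    """
    df = table
    if apply_exclusions:
        df = df[~(df["overestimated_gt"] | df["misaligned_applicator"])]
    if len(df) < 3:
        raise ValueError("need at least 3 included cases")
    whiskers = {}
    for indicator in ("rel_vol_diff", "hausdorff", "dice"):
        whiskers[indicator] = {
            "model": WhiskerSummary.from_values(df[f"{indicator}_model"]),
            "manufacturer": WhiskerSummary.from_values(df[f"{indicator}_manufacturer"]),
        }
    x = df["vol_manufacturer_ml"].to_numpy()
    y = df["vol_model_ml"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        r = None
    else:
        r = float(sps.pearsonr(x, y).statistic)
    return CohortSummary(
        n_included=len(df),
        n_excluded=len(table) - len(df),
        whiskers=whiskers,
        pearson_r_volumes=r,
        delta_rel_vol_diff=float(
            (df["rel_vol_diff_manufacturer"] - df["rel_vol_diff_model"]).mean()
        ),
        delta_hausdorff_mm=float(
            (df["hausdorff_manufacturer"] - df["hausdorff_model"]).mean()
        ),
        delta_dice=float((df["dice_model"] - df["dice_manufacturer"]).mean()),
    )
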