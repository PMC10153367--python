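import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mwaplan.cohort import (
    WhiskerSummary,
    aggregate,
    identity_rel_distance,
    make_cohort_table,
    split_by_vascular_fraction,
    tukey_groups,
    vf_threshold_scan,
)


def cohort_df(n=10, rng=None, vf=None, model_vol=None):
    rng = rng or np.random.default_rng(0)
    vols = rng.uniform(10.0, 30.0, n)
    rows = []
    for i in range(n):
        vm = model_vol[i] if model_vol is not None else vols[i]
        rows.append(
            {
                "case_id": f"C{i:03d}",
                "vol_model_ml": vm,
                "vol_manufacturer_ml": vols[i],
                "vol_gt_ml": vols[i] * 1.05,
                "dice_model": 0.9,
                "dice_manufacturer": 0.8,
                "hausdorff_model": 2.0,
                "hausdorff_manufacturer": 3.0,
                "rel_vol_diff_model": 0.05,
                "rel_vol_diff_manufacturer": 0.15,
                "vascular_fraction": vf[i] if vf is not None else 0.0,
                "overestimated_gt": False,
                "misaligned_applicator": False,
            }
        )
    return make_cohort_table(rows)


class TestIdentityRelDistance:
    def test_formula(self):
        assert identity_rel_distance(10.0, 12.0) == pytest.approx(0.2)

    def test_zero_on_identity_line(self):
        assert identity_rel_distance(7.5, 7.5) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            identity_rel_distance(0.0, 5.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        x=st.floats(0.1, 1e4),
        y=st.floats(0.0, 1e4),
        k=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, x, y, k):
        d1 = identity_rel_distance(x, y)
        d2 = identity_rel_distance(k * x, k * y)
        assert d2 == pytest.approx(d1, rel=1e-9, abs=1e-12)


class TestTukeyGroups:
    def test_identical_groups_not_significant(self):
        res = tukey_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.mean_difference == 0.0
        assert not res.significant

    def test_widely_separated_groups_significant(self):
        rng = np.random.default_rng(2)
        a = 10.0 + rng.normal(0, 0.01, 5)
        b = rng.normal(0, 0.01, 5)
        res = tukey_groups(a, b)
        assert res.significant
        assert res.ci_low > 0

    def test_degenerate_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            tukey_groups([1.0], [2.0, 3.0])

    def test_hand_sized_example_matches_textbook_formula(self):
        # fixed 4 + 4 fixture; CI from the studentized-range quantile by hand
        a = np.array([0.31, 0.28, 0.35, 0.30])
        b = np.array([0.05, 0.09, 0.02, 0.08])
        res = tukey_groups(a, b)
        msw = (np.var(a, ddof=1) * 3 + np.var(b, ddof=1) * 3) / 6
        q = sps.studentized_range.ppf(0.95, 2, 6)
        half = q * np.sqrt(msw / 2 * (1 / 4 + 1 / 4))
        diff = a.mean() - b.mean()
        assert res.mean_difference == pytest.approx(diff, rel=1e-12)
        assert res.ci_low == pytest.approx(diff - half, rel=1e-9)
        assert res.ci_high == pytest.approx(diff + half, rel=1e-9)
        assert res.significant

    def test_matches_statsmodels_tukeyhsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(7)
        a = rng.normal(0.4, 0.1, 6)
        b = rng.normal(0.1, 0.1, 9)
        res = tukey_groups(a, b)
        sm = pairwise_tukeyhsd(
            np.concatenate([a, b]), ["a"] * 6 + ["b"] * 9, alpha=0.05
        )
        # statsmodels reports group2 - group1
        assert -sm.meandiffs[0] == pytest.approx(res.mean_difference, rel=1e-9)
        assert -sm.confint[0][1] == pytest.approx(res.ci_low, rel=1e-6)
        assert -sm.confint[0][0] == pytest.approx(res.ci_high, rel=1e-6)
        assert bool(sm.reject[0]) == res.significant


class TestVfThresholdScan:
    def test_planted_onset_recovered(self):
        rng = np.random.default_rng(4)
        vf = np.array([0.0, 0.005, 0.01, 0.02, 0.03, 0.04, 0.06, 0.08, 0.10, 0.15])
        # effect switches on above 5% vascular fraction
        values = np.where(vf > 0.05, 0.30, 0.02) + rng.normal(0, 0.005, len(vf))
        df = cohort_df(n=10, vf=vf)
        threshold, results = vf_threshold_scan(df, np.abs(values), [0.01, 0.03, 0.05, 0.08])
        # recovered within one candidate step of the planted 5% onset
        assert threshold in (0.03, 0.05)
        assert results[0.05].significant
        assert not results[0.01].significant

    def test_no_effect_reports_none(self):
        rng = np.random.default_rng(9)
        vf = np.linspace(0.0, 0.15, 12)
        values = rng.normal(0.0, 0.01, 12)
        df = cohort_df(n=12, vf=vf)
        threshold, results = vf_threshold_scan(df, np.abs(values), [0.03, 0.05, 0.08])
        assert threshold is None
        assert results  # scans were performed and reported

    def test_all_cases_on_one_side_rejected(self):
        df = cohort_df(n=6, vf=np.zeros(6))
        with pytest.raises(ValueError):
            vf_threshold_scan(df, np.zeros(6), [0.05])


class TestAggregate:
    def test_identical_rows_zero_whiskers_and_undefined_r(self):
        df = cohort_df(n=5, model_vol=[20.0] * 5)
        df["vol_manufacturer_ml"] = 20.0
        summary = aggregate(df)
        w = summary.whiskers["dice"]["model"]
        assert w.q1 == w.q3 == w.median
        assert summary.pearson_r_volumes is None

    def test_model_equals_manufacturer_perfect_correlation(self):
        df = cohort_df(n=8)
        summary = aggregate(df)
        assert summary.pearson_r_volumes == pytest.approx(1.0)

    def test_quartiles_match_order_statistics_oracle(self):
        values = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0, 5.0])
        w = WhiskerSummary.from_values(values)
        s = np.sort(values)  # 11 values: quartiles at positions 2.5, 5, 7.5
        assert w.median == s[5]
        assert w.q1 == pytest.approx((s[2] + s[3]) / 2)
        assert w.q3 == pytest.approx((s[7] + s[8]) / 2)
        iqr = w.q3 - w.q1
        assert w.whisker_low == s[s >= w.q1 - 1.5 * iqr].min()
        assert w.whisker_high == s[s <= w.q3 + 1.5 * iqr].max()

    def test_exclusions_honoured(self):
        df = cohort_df(n=6)
        df.loc[0, "overestimated_gt"] = True
        df.loc[1, "misaligned_applicator"] = True
        incl = aggregate(df, apply_exclusions=True)
        assert incl.n_included == 4
        assert incl.n_excluded == 2
        assert aggregate(df, apply_exclusions=False).n_included == 6

    def test_too_few_cases_rejected(self):
        df = cohort_df(n=4)
        df.loc[:2, "overestimated_gt"] = True
        with pytest.raises(ValueError):
            aggregate(df, apply_exclusions=True)

    def test_paired_deltas_oriented_towards_model(self):
        df = cohort_df(n=5)
        summary = aggregate(df)
        assert summary.delta_dice == pytest.approx(0.1)
        assert summary.delta_hausdorff_mm == pytest.approx(1.0)
        assert summary.delta_rel_vol_diff == pytest.approx(0.1)


class TestSplitByVf:
    def test_partition_is_exhaustive_and_disjoint(self):
        vf = np.array([0.0, 0.02, 0.06, 0.08, 0.01, 0.2])
        df = cohort_df(n=6, vf=vf).assign(val=np.arange(6.0))
        hi, lo = split_by_vascular_fraction(df, 0.05, "val")
        assert len(hi) + len(lo) == 6
        assert set(hi) == {2.0, 3.0, 5.0}
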