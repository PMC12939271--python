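import math

import numpy as np
import pandas as pd
import pytest

from rootangle import (
    STUDY_COLLECTED,
    STUDY_EXCLUSIONS,
    bland_altman,
    dice,
    exclusion_accounting,
    grouped_errors,
    icc,
    interpret_icc,
    repeat_sensitivity,
)
from rootangle.agreement import ratings_table


def anova_icc_oracle(values):
    """Independent oracle: explicit sum-of-squares loops, no vectorization."""
    n, k = len(values), len(values[0])
    grand = sum(values[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(values[i]) / k for i in range(n)]
    col_means = [sum(values[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((values[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc31 = (msr - mse) / (msr + (k - 1) * mse)
    return icc21, icc31


class TestICC:
    def test_identical_columns_give_unity(self):
        t = np.column_stack([[1.0, 5, 9, 2], [1.0, 5, 9, 2]])
        assert icc(t, "two_way_random_2_1").icc == pytest.approx(1.0)
        assert icc(t, "two_way_mixed_3_1").icc == pytest.approx(1.0)

    @pytest.mark.parametrize("n, k, seed", [(5, 2, 0), (6, 2, 1), (8, 3, 2), (10, 3, 3)])
    def test_matches_brute_force_anova_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        subj = rng.normal(0, 5, n)
        table = subj[:, None] + rng.normal(0, 1, (n, k)) + rng.normal(0, 0.5, k)
        e21, e31 = anova_icc_oracle(table.tolist())
        assert icc(table, "two_way_random_2_1").icc == pytest.approx(e21, abs=1e-10)
        assert icc(table, "two_way_mixed_3_1").icc == pytest.approx(e31, abs=1e-10)

    def test_constant_offset_consistency_vs_absolute(self):
        rng = np.random.default_rng(4)
        a = rng.normal(10, 4, 12)
        table = np.column_stack([a, a + 3.0])
        assert icc(table, "two_way_mixed_3_1").icc == pytest.approx(1.0)
        assert icc(table, "two_way_random_2_1").icc < 1.0

    def test_matches_pingouin_estimates_and_intervals(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n, k = 15, 3
        table = rng.normal(0, 3, n)[:, None] + rng.normal(0, 1, (n, k))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "value": table.ravel(),
        })
        pg = pingouin.intraclass_corr(long, "subject", "rater", "value").set_index("Type")
        for model, pg_type in (("two_way_random_2_1", "ICC(A,1)"),
                               ("two_way_mixed_3_1", "ICC(C,1)")):
            res = icc(table, model)
            assert res.icc == pytest.approx(pg.loc[pg_type, "ICC"], abs=1e-8)
            lo, hi = pg.loc[pg_type, "CI95"]   # pingouin rounds to 2 decimals
            assert res.ci_low == pytest.approx(lo, abs=6e-3)
            assert res.ci_high == pytest.approx(hi, abs=6e-3)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(6)
        table = rng.normal(0, 2, 8)[:, None] + rng.normal(0, 1, (8, 2))
        for model in ("two_way_random_2_1", "two_way_mixed_3_1"):
            res = icc(table, model)
            assert res.ci_low <= res.icc <= res.ci_high

    def test_degenerate_all_identical(self):
        with pytest.warns(UserWarning, match="identical"):
            res = icc(np.full((5, 2), 3.0))
        assert res.icc == 1.0 and res.ci_low == res.ci_high == 1.0

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            icc(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            icc(np.array([[1.0, np.nan], [2, 3], [4, 5]]))
        with pytest.raises(ValueError):
            icc(np.zeros((4, 2)), model="one_way")

    @pytest.mark.parametrize("value, band", [
        (0.49, "poor"), (0.50, "moderate"), (0.75, "moderate"),
        (0.76, "good"), (0.90, "good"), (0.941, "excellent"),
    ])
    def test_interpretation_bands(self, value, band):
        assert interpret_icc(value) == band

    def test_ratings_table_pivot(self):
        long = pd.DataFrame({
            "subject": ["s1", "s1", "s2", "s2"],
            "rater": ["r1", "r2", "r1", "r2"],
            "value": [1.0, 2.0, 3.0, 4.0],
        })
        wide = ratings_table(long)
        assert wide.shape == (2, 2)
        with pytest.raises(ValueError, match="incomplete"):
            ratings_table(long.iloc[:3])


class TestBlandAltman:
    def test_identical_pairs(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = bland_altman(a, a)
        assert res.bias == 0 and res.loa_low == 0 and res.loa_high == 0

    def test_hand_computed_sample_sd(self):
        res = bland_altman([1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0])
        assert res.bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(2 / math.sqrt(3))
        assert res.loa_high == pytest.approx(1.96 * 2 / math.sqrt(3), abs=1e-9)

    def test_loa_width_and_antisymmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 3, 30), rng.normal(0, 3, 30)
        res = bland_altman(a, b)
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * res.sd_diff)
        assert res.bias == pytest.approx(-bland_altman(b, a).bias)

    def test_proportional_bias_detected(self):
        m = np.linspace(0, 10, 40)
        a = m + 0.3 * m          # difference grows with the mean
        res = bland_altman(a, m)
        assert res.proportional_bias_slope == pytest.approx(0.3, rel=0.15)
        assert res.proportional_bias_p < 0.01

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestDice:
    def test_identical_disjoint_and_half(self):
        a = np.zeros((20, 20), bool)
        a[0:10, 0:10] = True
        assert dice(a, a) == 1.0
        b = np.zeros((20, 20), bool)
        b[10:20, 10:20] = True
        assert dice(a, b) == 0.0
        c = np.zeros((20, 20), bool)
        c[0:10, 5:15] = True          # overlaps a in a 10x5 strip
        assert dice(a, c) == pytest.approx(0.5)

    def test_symmetry_and_vacuous_case(self):
        rng = np.random.default_rng(8)
        a = rng.random((15, 15)) > 0.5
        b = rng.random((15, 15)) > 0.5
        assert dice(a, b) == dice(b, a)
        with pytest.warns(UserWarning, match="empty"):
            assert dice(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


def _records_frame(angles, image_id="img1"):
    codes = ["13", "14", "15", "16", "17", "23", "24", "25", "26", "27",
             "33", "34", "35", "36", "37", "43", "44", "45", "46", "47"]
    return pd.DataFrame({
        "image_id": image_id,
        "fdi_code": codes[: len(angles)],
        "angle_deg": angles,
    })


class TestGroupedErrors:
    def test_perfect_agreement(self):
        ref = _records_frame(np.linspace(-8, 8, 20))
        out = grouped_errors(ref, ref, "tooth_type")
        assert (out.mae == 0).all()
        assert np.allclose(out.icc, 1.0)

    def test_constant_offset_mae(self):
        ref = _records_frame(np.linspace(-8, 8, 20))
        ai = ref.assign(angle_deg=ref.angle_deg + 0.5)
        for grouping in ("tooth_type", "arch", "side"):
            out = grouped_errors(ai, ref, grouping)
            assert out.mae.to_numpy() == pytest.approx(0.5)
        assert set(grouped_errors(ai, ref, "arch").group) == {"maxillary", "mandibular"}
        assert set(grouped_errors(ai, ref, "side").group) == {"left", "right"}

    def test_group_mae_ordering_follows_injected_noise(self):
        rng = np.random.default_rng(9)
        sds = {"canine": 0.1, "first premolar": 0.5, "second premolar": 1.0,
               "first molar": 2.0, "second molar": 4.0}
        frames = []
        for i in range(40):
            frames.append(_records_frame(rng.normal(0, 5, 20), f"img{i}"))
        ref = pd.concat(frames, ignore_index=True)
        from rootangle import FDISchema
        schema = FDISchema.default()
        ttype = [schema.lookup(schema.class_of(c)).tooth_type for c in ref.fdi_code]
        noise = np.array([rng.normal(0, sds[t]) for t in ttype])
        ai = ref.assign(angle_deg=ref.angle_deg + noise)
        out = grouped_errors(ai, ref, "tooth_type").set_index("group")
        order = ["canine", "first premolar", "second premolar",
                 "first molar", "second molar"]
        maes = out.loc[order, "mae"].to_numpy()
        assert (np.diff(maes) > 0).all()

    def test_unmatched_records_dropped(self):
        ref = _records_frame(np.arange(20.0))
        ai = _records_frame(np.arange(20.0), image_id="other")
        with pytest.raises(ValueError, match="no matched"):
            grouped_errors(ai, ref)


class TestRepeatSensitivity:
    def test_identical_runs(self):
        run = _records_frame(np.linspace(-5, 5, 20))
        rep = repeat_sensitivity(run, run)
        assert rep.mean_abs_diff == rep.p95_abs_diff == rep.max_abs_diff == 0
        assert rep.frac_gt_1deg == rep.frac_gt_2deg == 0
        assert rep.n_teeth == 20

    def test_direct_arithmetic(self):
        run1 = _records_frame([0.0, 0.0, 0.0, 0.0])
        run2 = _records_frame([0.5, 1.5, 2.5, 3.5])
        rep = repeat_sensitivity(run1, run2)
        assert rep.mean_abs_diff == pytest.approx(2.0)
        assert rep.max_abs_diff == pytest.approx(3.5)
        assert rep.frac_gt_1deg == pytest.approx(0.75)
        assert rep.frac_gt_2deg == pytest.approx(0.5)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(10)
        run1 = _records_frame(rng.normal(0, 5, 20))
        run2 = _records_frame(rng.normal(0, 5, 20))
        rep = repeat_sensitivity(run1, run2)
        assert rep.mean_abs_diff <= rep.p95_abs_diff <= rep.max_abs_diff
        assert rep.frac_gt_2deg <= rep.frac_gt_1deg


class TestExclusionAccounting:
    def test_study_accounting_reaches_214(self):
        assert exclusion_accounting(STUDY_COLLECTED, STUDY_EXCLUSIONS) == 214

    def test_empty_list_is_identity(self):
        assert exclusion_accounting(100, []) == 100

    def test_overdrawn_counts_rejected(self):
        with pytest.raises(ValueError):
            exclusion_accounting(10, [("a", 7), ("b", 5)])
        with pytest.raises(ValueError):
            exclusion_accounting(10, [("a", -1)])
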