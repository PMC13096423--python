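"""Preprocessing stages against hand-computed and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metabrescue.preprocess import (
    PreprocessConfig,
    boxcox_transform,
    compute_indicators,
    compute_lod,
    filter_below_lod,
    normalize_plates,
    run_preprocessing,
    standardize,
    tukey_fence,
)
from metabrescue.synthetic import PlantedTruth, StudyDesign, generate_study
from metabrescue.tables import AnalyteTable, IndicatorFormula, LodTable, ValidationError

from conftest import make_table


def _plate_table(qc_values, study_values, expected=1.0, n_plates=1):
    """One analyte, one plate (or more), hand-set QC and study values."""
    rows, meta = [], []
    for p in range(n_plates):
        for i, v in enumerate(qc_values[p]):
            rows.append(v)
            meta.append({"subject": None, "genotype": None, "treatment": None,
                         "group": None, "sex": None, "tissue": None, "plate": p, "role": "qc"})
        for i, v in enumerate(study_values[p]):
            rows.append(v)
            meta.append({"subject": f"s{p}_{i}", "genotype": "WT", "treatment": "vehicle",
                         "group": "WT-vehicle", "sex": "male", "tissue": "plasma",
                         "plate": p, "role": "study"})
    values = pd.DataFrame({"A": rows}, index=[f"w{i}" for i in range(len(rows))])
    meta = pd.DataFrame(meta, index=values.index)
    am = pd.DataFrame({"method": ["UHPLC"], "kind": ["metabolite"],
                       "class_label": ["x"], "expected_qc": [expected]}, index=["A"])
    return AnalyteTable(values, meta, am)


class TestPlateNormalization:
    def test_qc_median_double_expected_halves_study_values(self):
        t = _plate_table([[2.0, 2.0, 2.0]], [[4.0, 8.0]], expected=1.0)
        out = normalize_plates(t)
        study = out.sample_meta["role"] == "study"
        assert list(out.values.loc[study, "A"]) == [2.0, 4.0]

    def test_qc_median_equal_expected_is_identity(self):
        t = _plate_table([[1.0, 1.0]], [[4.0, 8.0]], expected=1.0)
        out = normalize_plates(t)
        study = out.sample_meta["role"] == "study"
        assert list(out.values.loc[study, "A"]) == [4.0, 8.0]

    def test_planted_biases_equalize_cross_plate_qc_medians(self):
        """Plates with biases 0.5 and 2.0: post-normalization QC medians
        agree across plates (oracle = direct median on generated wells)."""
        design = StudyDesign(
            n_per_group_per_sex=4, tissues=("plasma",), n_metabolites=10,
            n_plates=2, qc_per_plate=5, plate_biases=(0.5, 2.0), seed=21,
        )
        s = generate_study(design, PlantedTruth())
        out = normalize_plates(s.table)
        qc = out.sample_meta["role"] == "qc"
        med0 = out.values.loc[qc & (out.sample_meta["plate"] == 0)].median()
        med1 = out.values.loc[qc & (out.sample_meta["plate"] == 1)].median()
        assert np.allclose(med0, med1, rtol=1e-6)

    def test_raw_qc_kept_in_provenance(self):
        t = _plate_table([[2.0, 2.0]], [[4.0]], expected=1.0)
        out = normalize_plates(t)
        assert (out.provenance["raw_qc_blank"]["A"] == 2.0).all()

    def test_plate_without_qc_raises(self):
        t = _plate_table([[2.0]], [[4.0]], expected=1.0)
        t.sample_meta.loc[t.sample_meta["role"] == "qc", "role"] = "blank"
        with pytest.raises(ValidationError, match="no QC"):
            normalize_plates(t)


class TestLod:
    def test_three_times_median_rule(self):
        lods = compute_lod({"A": [1, 2, 9]})
        assert lods.lod["A"] == 6.0

    def test_all_zero_blanks_give_zero_lod(self):
        lods = compute_lod({"A": [0.0, 0.0, 0.0]})
        assert lods.lod["A"] == 0.0

    def test_matches_sort_based_median(self):
        rng = np.random.default_rng(1)
        draws = rng.lognormal(0, 1, 51)
        lods = compute_lod({"A": draws})
        s = np.sort(draws)
        assert lods.lod["A"] == pytest.approx(3 * s[25])

    def test_empty_blanks_error(self):
        with pytest.raises(ValidationError):
            compute_lod(pd.DataFrame(columns=["A"]))


def _filter_fixture(fracs_by_group):
    """One analyte per entry; 10 samples per group; values below/above LOD=1."""
    groups = ["WT-vehicle", "WT-FTY720", "APP/PS1-vehicle", "APP/PS1-FTY720"]
    rows, meta = [], []
    i = 0
    for g, frac in zip(groups, fracs_by_group):
        genotype, treatment = g.rsplit("-", 1)
        n_below = int(round(frac * 10))
        for k in range(10):
            rows.append(0.5 if k < n_below else 2.0)
            meta.append({"subject": f"s{i}", "genotype": genotype, "treatment": treatment,
                         "group": g, "sex": "male", "tissue": "plasma", "plate": 0,
                         "role": "study"})
            i += 1
    values = pd.DataFrame({"A": rows}, index=[f"w{j}" for j in range(len(rows))])
    meta = pd.DataFrame(meta, index=values.index)
    return make_table(values, meta)


class TestLodFilter:
    lods = LodTable(lod=pd.Series({"A": 1.0}), source_n_blanks=3)

    def test_above_half_in_all_groups_removed(self):
        t = _filter_fixture([0.6, 0.6, 0.6, 0.6])
        out, report = filter_below_lod(t, self.lods, ("group",))
        assert "A" not in out.analytes
        assert report.loc["A", "removed"]

    def test_one_clean_group_retains(self):
        t = _filter_fixture([0.6, 0.6, 0.6, 0.0])
        out, _ = filter_below_lod(t, self.lods, ("group",))
        assert "A" in out.analytes

    def test_exactly_half_everywhere_retained(self):
        t = _filter_fixture([0.5, 0.5, 0.5, 0.5])
        out, _ = filter_below_lod(t, self.lods, ("group",))
        assert "A" in out.analytes

    def test_surviving_below_lod_values_unchanged(self):
        t = _filter_fixture([0.5, 0.5, 0.5, 0.5])
        out, _ = filter_below_lod(t, self.lods, ("group",))
        pd.testing.assert_series_equal(out.values["A"], t.values["A"])

    def test_unknown_subgroup_key_errors(self):
        t = _filter_fixture([0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValidationError, match="cage"):
            filter_below_lod(t, self.lods, ("cage",))


def _indicator_table(data: dict):
    n = len(next(iter(data.values())))
    values = pd.DataFrame(data, index=[f"w{i}" for i in range(n)])
    meta = pd.DataFrame(
        {"subject": [f"s{i}" for i in range(n)], "genotype": "WT", "treatment": "vehicle",
         "group": "WT-vehicle", "sex": "male", "tissue": "plasma", "plate": 0,
         "role": "study"},
        index=values.index,
    )
    return make_table(values, meta)


class TestIndicators:
    def test_spermidine_synthesis_ratio(self):
        t = _indicator_table({"spermidine": [4.0], "putrescine": [2.0]})
        f = IndicatorFormula("spermidine synthesis", "ratio", ("spermidine",), ("putrescine",))
        out, skipped = compute_indicators(t, [f])
        assert not skipped
        assert out.values["spermidine synthesis"].iloc[0] == 2.0
        assert out.analyte_meta.loc["spermidine synthesis", "kind"] == "indicator"

    def test_zero_denominator_is_missing(self):
        t = _indicator_table({"a": [4.0], "b": [0.0]})
        out, _ = compute_indicators(t, [IndicatorFormula("r", "ratio", ("a",), ("b",))])
        assert np.isnan(out.values["r"].iloc[0])

    def test_missing_component_propagates(self):
        t = _indicator_table({"a": [4.0, np.nan], "b": [1.0, 1.0]})
        out, _ = compute_indicators(t, [IndicatorFormula("s", "sum", ("a", "b"))])
        assert out.values["s"].iloc[0] == 5.0
        assert np.isnan(out.values["s"].iloc[1])

    def test_unknown_component_skips_with_warning(self):
        t = _indicator_table({"a": [4.0]})
        out, skipped = compute_indicators(
            t, [IndicatorFormula("bad", "ratio", ("a",), ("gone",))]
        )
        assert skipped == ["bad"]
        assert "bad" not in out.analytes

    @given(st.lists(st.floats(0.1, 100), min_size=3, max_size=3))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_reevaluation(self, vals):
        t = _indicator_table({"a": [vals[0]], "b": [vals[1]], "c": [vals[2]]})
        formulas = [
            IndicatorFormula("sum_abc", "sum", ("a", "b", "c")),
            IndicatorFormula("ratio", "ratio", ("a", "b"), ("c",)),
        ]
        out, _ = compute_indicators(t, formulas)
        assert out.values["sum_abc"].iloc[0] == pytest.approx(sum(vals))
        assert out.values["ratio"].iloc[0] == pytest.approx((vals[0] + vals[1]) / vals[2])


class TestBoxCox:
    def test_lognormal_sample_gives_lambda_near_zero(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(0, 1, 500))
        _, lam = boxcox_transform(x)
        assert lam == pytest.approx(0.0, abs=0.15)

    def test_shifted_normal_gives_lambda_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 500)
        x = x - x.min() + 0.05  # shifted just into positivity
        _, lam = boxcox_transform(x)
        assert lam == pytest.approx(1.0, abs=0.3)
        # independent oracle: scipy's own unconstrained MLE
        _, lam_scipy = stats.boxcox(x)
        assert lam == pytest.approx(lam_scipy, abs=0.02)

    def test_grid_llf_matches_scipy_boxcox_llf(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(1, 0.5, 80)
        from metabrescue.preprocess import _boxcox_llf_grid

        grid = np.array([-2.0, -0.5, 0.0, 0.7, 1.0, 2.5])
        mine = _boxcox_llf_grid(x, grid)
        ref = np.array([stats.boxcox_llf(l, x) for l in grid])
        assert np.allclose(mine, ref, rtol=1e-10)

    @given(st.lists(st.floats(0.01, 1e4), min_size=6, max_size=40, unique=True))
    @settings(max_examples=25, deadline=None)
    def test_rank_order_preserved(self, vals):
        x = np.asarray(vals)
        transformed, _ = boxcox_transform(x)
        order = np.argsort(x, kind="stable")
        assert (np.diff(transformed.to_numpy()[order]) >= -1e-12).all()

    def test_nonpositive_with_error_policy_raises(self):
        with pytest.raises(ValidationError, match="nonpositive"):
            boxcox_transform(np.array([-1.0, 1, 2, 3, 4, 5]), shift_policy="error")

    def test_too_few_values_raises(self):
        with pytest.raises(ValidationError):
            boxcox_transform(np.array([1.0, 2.0, 3.0]))


class TestTukeyFence:
    def test_values_within_fences_unchanged(self):
        x = np.arange(1.0, 10.0)
        out = tukey_fence(x)
        assert (out.to_numpy() == x).all()

    def test_remote_outlier_clamped_to_hand_computed_fence(self):
        # n = 10, linear interpolation between order statistics:
        # Q1 at position 0.25*(10-1) = 2.25 -> 3 + 0.25*(4-3) = 3.25
        # Q3 at position 0.75*(10-1) = 6.75 -> 7 + 0.75*(8-7) = 7.75
        # IQR = 4.5, upper fence = 7.75 + 3*4.5 = 21.25
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 1000.0])
        out = tukey_fence(x, k=3)
        assert out.iloc[-1] == pytest.approx(21.25)
        assert (out.iloc[:-1].to_numpy() == x[:-1]).all()

    def test_constant_vector_untouched(self):
        x = np.full(8, 3.0)
        assert (tukey_fence(x).to_numpy() == x).all()

    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=50))
    @settings(max_examples=40, deadline=None)
    def test_idempotent(self, vals):
        x = np.asarray(vals)
        once = tukey_fence(x)
        twice = tukey_fence(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), equal_nan=True)


class TestStandardize:
    def test_reference_mean_zero_sd_one(self):
        x = pd.Series([1.0, 2.0, 3.0, 10.0])
        mask = np.array([True, True, True, False])
        z = standardize(x, mask)
        assert z[mask].mean() == pytest.approx(0.0)
        assert z[mask].std(ddof=1) == pytest.approx(1.0)

    def test_value_at_reference_mean_maps_to_zero(self):
        z = standardize(pd.Series([1.0, 3.0, 2.0]), np.array([True, True, False]))
        assert z.iloc[2] == pytest.approx(0.0)

    def test_planted_one_sd_shift_recovered(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(0, 2, 500)
        shifted = rng.normal(2 * 1.0, 2, 500)  # +1 reference SD
        x = pd.Series(np.concatenate([ref, shifted]))
        mask = np.arange(1000) < 500
        z = standardize(x, mask)
        assert z[~mask].mean() == pytest.approx(1.0, abs=0.15)

    def test_zero_reference_sd_raises(self):
        with pytest.raises(ValidationError):
            standardize(pd.Series([1.0, 1.0, 5.0]), np.array([True, True, False]))


class TestFullChain:
    def test_stage_order_logged(self, null_study):
        res = run_preprocessing(null_study.table)
        stages = res.table.provenance["stages"]
        assert stages.index("normalize_plates") < stages.index("compute_indicators")
        assert stages[-3:] == ["boxcox_transform", "tukey_fence", "standardize"]

    def test_null_data_standardized_group_means_near_zero(self):
        """No planted effects: per-analyte standardized group means are
        within 3 SE of zero for >= 95% of analyte x tissue cells. Enough
        QC repeats are used that plate-factor estimation noise is small
        relative to biological scatter."""
        design = StudyDesign(
            n_per_group_per_sex=6, tissues=("frontal cortex", "plasma"),
            n_metabolites=40, qc_per_plate=8, seed=17,
        )
        null_study = generate_study(design, PlantedTruth())
        res = run_preprocessing(null_study.table)
        meta = res.table.sample_meta
        checks = []
        for g in ("APP/PS1-vehicle", "WT-FTY720", "APP/PS1-FTY720"):
            sel = meta["group"] == g
            for tissue in res.table.tissues:
                sub = res.table.values.loc[sel & (meta["tissue"] == tissue)]
                m = sub.mean()
                se = sub.std() / np.sqrt(sub.notna().sum())
                checks.extend((m.abs() <= 3 * se).tolist())
        assert np.mean(checks) >= 0.95

    def test_reference_group_standardized_exactly(self, null_study):
        res = run_preprocessing(null_study.table)
        meta = res.table.sample_meta
        for tissue in res.table.tissues:
            ref = res.table.values.loc[
                (meta["group"] == "WT-vehicle") & (meta["tissue"] == tissue)
            ]
            assert np.allclose(ref.mean(), 0.0, atol=1e-10)
            assert np.allclose(ref.std(ddof=1), 1.0, atol=1e-10)

    def test_indicators_computed_after_filter(self, null_study):
        formulas = [IndicatorFormula("r01", "ratio", ("M000",), ("M001",))]
        res = run_preprocessing(null_study.table, formulas)
        assert "r01" in res.table.analytes
        assert res.table.analyte_meta.loc["r01", "kind"] == "indicator"
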