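"""Preprocessing rules: the 25% missingness filter, imputation heuristics,
scaler selection, variance filter, encodings, and fit/apply leakage hygiene."""

import numpy as np
import pandas as pd
import pytest

from pathoftt import (
    PreprocessConfig,
    apply_preprocessor,
    fit_preprocessor,
)
from pathoftt.preprocess import (
    ContractError,
    KeywordRule,
    choose_imputation,
    choose_scaler,
    drop_high_missingness,
    variance_filter,
)
from pathoftt.table_io import AnnotatedVariantTable, ColumnSpec, SchemaError


def _table(columns: dict, kinds: dict, orders: dict | None = None):
    specs = []
    data = {}
    for name, values in columns.items():
        kind = kinds[name]
        specs.append(
            ColumnSpec(
                name, kind,
                ordinal_order=(orders or {}).get(name),
            )
        )
        if kind == "numerical":
            data[name] = pd.Series(values, dtype="float64")
        else:
            data[name] = pd.Series(values, dtype="string")
    return AnnotatedVariantTable(specs=specs, data=pd.DataFrame(data))


class TestMissingnessFilter:
    @pytest.mark.parametrize(
        "missing_count,expect_dropped",
        [(6, True), (5, False), (0, False)],  # 30%, exactly 25%, 0% of n=20
    )
    def test_strict_threshold(self, missing_count, expect_dropped):
        values = [np.nan] * missing_count + [1.0 * i for i in range(20 - missing_count)]
        table = _table({"x": values, "y": list(range(20))},
                       {"x": "numerical", "y": "numerical"})
        _, dropped = drop_high_missingness(table, threshold=0.25)
        assert ("x" in dropped) is expect_dropped
        assert "y" not in dropped


class TestChooseImputation:
    def test_worst_case_hint_fills_extreme(self):
        vals = np.array([0.0, 0.2, np.nan, 0.9])
        rule = choose_imputation(vals, domain_hint="low_is_worst")
        assert rule.kind == "worst_case"
        assert rule.fill_value == 0.0
        rule_hi = choose_imputation(vals, domain_hint="high_is_worst")
        assert rule_hi.fill_value == 0.9

    def test_normal_sample_gets_mean(self):
        vals = np.random.default_rng(0).standard_normal(1000)
        rule = choose_imputation(vals)
        assert rule.kind == "mean"
        assert rule.fill_value == pytest.approx(vals.mean())

    def test_skewed_sample_gets_median(self):
        vals = np.random.default_rng(0).lognormal(0, 1.0, 1000)
        from scipy import stats

        assert stats.skew(vals) > 1  # premise of the heuristic
        rule = choose_imputation(vals)
        assert rule.kind == "median"
        assert rule.fill_value == pytest.approx(np.median(vals))

    def test_all_missing_is_contract_error(self):
        with pytest.raises(ContractError):
            choose_imputation(np.array([np.nan, np.nan]))


class TestChooseScaler:
    def test_min_max_affine_map(self):
        vals = np.random.default_rng(0).lognormal(0, 1.5, 500)  # forces min_max
        rule = choose_scaler(vals)
        assert rule.kind == "min_max"
        out = rule.transform(np.array([vals.min(), vals.max()]))
        np.testing.assert_allclose(out, [0.0, 1.0])
        scaled = rule.transform(vals)
        assert scaled.min() == 0.0 and scaled.max() == 1.0

    def test_standard_scaling_moments(self):
        vals = np.random.default_rng(1).standard_normal(2000) * 3 + 7
        rule = choose_scaler(vals)
        assert rule.kind == "standard"
        out = rule.transform(vals)
        assert abs(out.mean()) < 1e-9
        assert abs(out.std(ddof=0) - 1) < 1e-9

    def test_out_of_range_passes_through_unclipped(self):
        vals = np.random.default_rng(0).lognormal(0, 1.5, 500)
        rule = choose_scaler(vals)
        assert rule.transform(np.array([vals.max() * 2]))[0] > 1.0

    def test_constant_column_rejected(self):
        with pytest.raises(ContractError):
            choose_scaler(np.full(10, 3.0))


class TestVarianceFilter:
    def test_constant_dropped_at_zero_threshold(self):
        num = pd.DataFrame({"const": np.ones(50), "ok": np.arange(50.0)})
        dropped = variance_filter(num, pd.DataFrame(), threshold=0.0)
        assert dropped == ["const"]

    def test_balanced_binary_kept(self):
        num = pd.DataFrame({"b": np.tile([0.0, 1.0], 50)})  # variance 0.25
        assert variance_filter(num, pd.DataFrame(), threshold=0.01) == []

    def test_variance_exactly_threshold_dropped(self):
        col = np.tile([0.0, 1.0], 50)
        dropped = variance_filter(
            pd.DataFrame({"b": col}), pd.DataFrame(), threshold=0.25
        )
        assert dropped == ["b"]

    def test_dominant_category_dropped(self):
        # majority frequency 0.999 exceeds 1 - threshold for threshold 0.01
        codes = pd.DataFrame({"c": [0] * 999 + [1]})
        assert variance_filter(pd.DataFrame(), codes, threshold=0.01) == ["c"]
        assert variance_filter(pd.DataFrame(), codes, threshold=1e-4) == []


class TestEncodings:
    def test_ordinal_rank_codes(self):
        table = _table(
            {"grade": ["low", "medium", "high", "medium"], "x": [1.0, 2.0, 3.0, 4.0]},
            {"grade": "categorical_ordinal", "x": "numerical"},
            orders={"grade": ("low", "medium", "high")},
        )
        fitted = fit_preprocessor(table, PreprocessConfig(variance_threshold=0.0))
        design = apply_preprocessor(fitted, table)
        grade_col = design.X_cat[:, design.categorical_names.index("grade")]
        np.testing.assert_array_equal(grade_col, [0, 1, 2, 1])

    def test_keyword_substring_match(self):
        rule = KeywordRule(("pathogenic",))
        out = rule.encode(pd.Series(
            ["likely_pathogenic_variant", "benign", None, "PATHOGENIC"],
            dtype="string",
        ))
        np.testing.assert_array_equal(out, [1.0, 0.0, 0.0, 1.0])

    def test_unseen_category_maps_to_unknown(self):
        train = _table({"c": ["a", "b", "a", "b"], "x": [1.0, 2.0, 3.0, 4.0]},
                       {"c": "categorical_nominal", "x": "numerical"})
        fitted = fit_preprocessor(train, PreprocessConfig(variance_threshold=0.0))
        test = _table({"c": ["a", "zzz", None, "b"], "x": [1.0, 2.0, 3.0, 4.0]},
                      {"c": "categorical_nominal", "x": "numerical"})
        design = apply_preprocessor(fitted, test)
        enc = fitted.encodings["c"]
        codes = design.X_cat[:, 0]
        assert codes[1] == enc.unknown_code
        assert codes[2] == enc.categories.index("__missing__")
        assert codes[0] != codes[3]

    def test_one_hot_option(self):
        train = _table({"c": ["a", "b", "a", "b"], "x": [1.0, 2.0, 3.0, 4.0]},
                       {"c": "categorical_nominal", "x": "numerical"})
        fitted = fit_preprocessor(
            train,
            PreprocessConfig(variance_threshold=0.0, one_hot_columns=("c",)),
        )
        design = apply_preprocessor(fitted, train)
        assert design.X_cat.shape[1] == 0
        a_col = design.X_num[:, design.numerical_names.index("c=a")]
        np.testing.assert_array_equal(a_col, [1.0, 0.0, 1.0, 0.0])


class TestFitApply:
    def _split_tables(self, small_table):
        _, table, _ = small_table
        n = table.n_rows
        train = table.subset_rows(np.arange(0, n // 2))
        test = table.subset_rows(np.arange(n // 2, n))
        return train, test

    def test_apply_is_total(self, small_table):
        train, test = self._split_tables(small_table)
        fitted = fit_preprocessor(train)
        for tab in (train, test):
            design = apply_preprocessor(fitted, tab)
            assert not np.isnan(design.X_num).any()
            assert (design.X_cat >= 0).all()

    def test_no_leakage_from_held_out_rows(self, small_table):
        # fitted parameters and train-split output must not move when
        # held-out rows are perturbed
        train, test = self._split_tables(small_table)
        fitted = fit_preprocessor(train)
        ref = apply_preprocessor(fitted, train)

        perturbed = test.data.copy()
        for col in test.columns_of_kind("numerical"):
            perturbed[col] = perturbed[col] * 100 + 5
        test2 = AnnotatedVariantTable(specs=list(test.specs), data=perturbed)

        fitted2 = fit_preprocessor(train)  # fit never saw test rows at all
        assert fitted2.to_json() == fitted.to_json()
        out = apply_preprocessor(fitted2, train)
        np.testing.assert_array_equal(out.X_num, ref.X_num)
        # and applying to the perturbed held-out rows uses training statistics
        d1 = apply_preprocessor(fitted, test)
        d2 = apply_preprocessor(fitted, test2)
        assert not np.allclose(d1.X_num, d2.X_num)

    def test_validation_uses_training_means(self):
        rng = np.random.default_rng(0)
        tr_vals = rng.standard_normal(200)
        train = _table({"x": tr_vals}, {"x": "numerical"})
        fitted = fit_preprocessor(train, PreprocessConfig(variance_threshold=0.0))
        val = _table({"x": [5.0]}, {"x": "numerical"})
        design = apply_preprocessor(fitted, val)
        expected = (5.0 - tr_vals.mean()) / tr_vals.std(ddof=0)
        assert design.X_num[0, 0] == pytest.approx(expected)

    def test_fit_deterministic_serialization(self, small_table):
        train, _ = self._split_tables(small_table)
        a = fit_preprocessor(train).to_json()
        b = fit_preprocessor(train).to_json()
        assert a == b

    def test_json_round_trip(self, small_table):
        from pathoftt import FittedPreprocessor

        train, test = self._split_tables(small_table)
        fitted = fit_preprocessor(train)
        restored = FittedPreprocessor.from_json(fitted.to_json())
        d1 = apply_preprocessor(fitted, test)
        d2 = apply_preprocessor(restored, test)
        np.testing.assert_array_equal(d1.X_num, d2.X_num)
        np.testing.assert_array_equal(d1.X_cat, d2.X_cat)

    def test_missing_kept_column_is_schema_error(self, small_table):
        train, test = self._split_tables(small_table)
        fitted = fit_preprocessor(train)
        crippled = test.select_columns(
            [c for c in test.data.columns if c != fitted.kept_numerical[0]]
        )
        with pytest.raises(SchemaError):
            apply_preprocessor(fitted, crippled)
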