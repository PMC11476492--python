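import numpy as np
import pandas as pd
import pytest

from perisk.cohort import CohortSpec, generate_cohort, inject_missingness
from perisk.encoding import FEATURE_COLUMNS, DERIVED_COLUMNS, encode
from perisk.imputation import (
    DEPENDENT_PAIRS,
    GESTATIONAL_STRATA_DAYS,
    ImputationModel,
    ImputerConfig,
    fit_imputer,
    impute_test,
    impute_train,
    stratum_of,
)

FAST = ImputerConfig(use_relations=False)


def brute_median(values):
    """Exhaustive independent median: mean of middle order statistics."""
    vals = sorted(v for v in values if not (isinstance(v, float) and np.isnan(v)))
    n = len(vals)
    if n == 0:
        return None
    if n % 2:
        return vals[n // 2]
    return (vals[n // 2 - 1] + vals[n // 2]) / 2


class TestStrata:
    def test_five_disjoint_ordered_intervals(self):
        assert len(GESTATIONAL_STRATA_DAYS) == 5
        for (lo1, hi1), (lo2, hi2) in zip(
            GESTATIONAL_STRATA_DAYS, GESTATIONAL_STRATA_DAYS[1:]
        ):
            assert lo1 <= hi1 < lo2 <= hi2

    def test_interval_bounds_in_weeks(self):
        # 11-13+6, 14-18+6, 19-23+6, 24-28+6, 29-33+6 weeks in days
        assert GESTATIONAL_STRATA_DAYS[0] == (7 * 11, 7 * 13 + 6)
        assert GESTATIONAL_STRATA_DAYS[-1] == (7 * 29, 7 * 33 + 6)

    def test_out_of_range_days_clamp_to_nearest(self):
        assert stratum_of(10) == 0
        assert stratum_of(300) == 4
        assert stratum_of(100) == 1


class TestFitImputer:
    def test_median_example(self):
        # class-0 {1,2,3}, class-1 {10,20}: intra {0:2, 1:15}, overall 3
        spec = CohortSpec(n_cases=2, n_controls=3, missing_rate=0.0, seed=0)
        table = generate_cohort(spec)
        table["age"] = [np.nan] * 5
        table.loc[table["label"] == "control", "age"] = [1.0, 2.0, 3.0]
        table.loc[table["label"] == "case", "age"] = [10.0, 20.0]
        model = fit_imputer(encode(table), FAST)
        assert model.intra_class_medians["age"][0] == 2.0
        assert model.intra_class_medians["age"][1] == 15.0
        assert model.overall_medians["age"] == 3.0

    def test_medians_match_brute_force_on_small_tables(self, small_cohort):
        table = small_cohort.head(50)
        enc = encode(table)
        model = fit_imputer(enc, FAST)
        y = enc.labels.to_numpy()
        for feat in FEATURE_COLUMNS:
            col = enc.frame[feat]
            assert model.overall_medians[feat] == brute_median(col.tolist())
            for label in (0, 1):
                expected = brute_median(col[y == label].tolist())
                assert model.intra_class_medians[feat][label] == expected

    def test_exact_linear_pair_learned(self):
        # complete matrix, current = 2 * pre: regressor must track the line
        spec = CohortSpec(
            n_cases=40, n_controls=60, missing_rate=0.0, pair_noise_sd=0.0, seed=1
        )
        table = generate_cohort(spec)
        table["current_weight"] = 2.0 * table["pre_pregnancy_weight"]
        enc = encode(table)
        model = fit_imputer(enc, ImputerConfig(min_pairs=5))
        net = model.net("weight", "pooled", None, "a_to_b")
        if net is None:  # pooled unstratified cell is not fitted; use stratum
            found = [
                model.net("weight", "pooled", s, "a_to_b")
                for s in range(5)
                if model.net("weight", "pooled", s, "a_to_b") is not None
            ]
            assert found, "no weight regressor was fitted"
            net = found[0]
        x = np.linspace(
            table["pre_pregnancy_weight"].quantile(0.1),
            table["pre_pregnancy_weight"].quantile(0.9),
            20,
        )
        np.testing.assert_allclose(net.predict(x), 2.0 * x, atol=1e-2)

    def test_regressors_fit_only_with_enough_pairs(self, small_cohort):
        model = fit_imputer(encode(small_cohort), ImputerConfig(min_pairs=10**6))
        assert not model.pair_nets

    def test_unlabelled_matrix_rejected(self, small_cohort):
        enc = encode(small_cohort).without_labels()
        with pytest.raises(ValueError):
            fit_imputer(enc, FAST)

    def test_model_json_round_trip(self, small_cohort):
        model = fit_imputer(encode(small_cohort), ImputerConfig(min_pairs=10))
        loaded = ImputationModel.from_json(model.to_json())
        assert loaded.overall_medians == model.overall_medians
        assert loaded.intra_class_medians == model.intra_class_medians
        assert set(loaded.pair_nets) == set(model.pair_nets)
        for key, net in model.pair_nets.items():
            np.testing.assert_allclose(loaded.pair_nets[key].w1, net.w1)


class TestImputeTrain:
    def test_intra_class_median_fill(self):
        spec = CohortSpec(n_cases=4, n_controls=3, missing_rate=0.0, seed=0)
        table = generate_cohort(spec)
        table.loc[table["label"] == "case", "age"] = [25.0, 30.0, 41.0, np.nan]
        enc = encode(table)
        model = fit_imputer(enc, FAST)
        out = impute_train(enc, model)
        case_rows = enc.labels.to_numpy() == 1
        filled = out.frame.loc[case_rows, "age"]
        assert 30.0 in filled.tolist()  # the missing case got the case median
        assert out.frame["age"].notna().all()

    def test_noiseless_pressure_relation_used(self):
        spec = CohortSpec(
            n_cases=50, n_controls=100, missing_rate=0.0, pair_noise_sd=0.0,
            bp_slope=1.0, bp_intercept=40.0, seed=2,
        )
        table = generate_cohort(spec)
        enc = encode(table)
        model = fit_imputer(enc, ImputerConfig(min_pairs=10))
        # knock out systolic on a few rows, keep diastolic
        masked = enc.copy()
        hit = [3, 10, 20]
        truth = masked.frame.loc[hit, "systolic_pressure"].to_numpy()
        masked.frame.loc[hit, "systolic_pressure"] = np.nan
        out = impute_train(masked, model)
        np.testing.assert_allclose(
            out.frame.loc[hit, "systolic_pressure"].to_numpy(), truth, atol=1e-2
        )

    def test_both_pair_members_missing_get_intra_class_medians(self):
        spec = CohortSpec(n_cases=20, n_controls=30, missing_rate=0.0, seed=3)
        table = generate_cohort(spec)
        enc = encode(table)
        model = fit_imputer(enc, FAST)
        masked = enc.copy()
        masked.frame.loc[0, "pre_pregnancy_weight"] = np.nan
        masked.frame.loc[0, "current_weight"] = np.nan
        out = impute_train(masked, model)
        label = int(enc.labels.iloc[0])
        assert out.frame.loc[0, "pre_pregnancy_weight"] == model.intra_class_medians[
            "pre_pregnancy_weight"
        ][label]
        assert out.frame.loc[0, "current_weight"] == model.intra_class_medians[
            "current_weight"
        ][label]

    def test_no_missing_input_is_identity(self, complete_cohort):
        enc = encode(complete_cohort)
        model = fit_imputer(enc, FAST)
        out = impute_train(enc, model)
        pd.testing.assert_frame_equal(out.frame, enc.frame)

    def test_output_complete_and_idempotent(self, small_cohort):
        enc = encode(small_cohort)
        model = fit_imputer(enc, ImputerConfig(min_pairs=10))
        once = impute_train(enc, model)
        assert once.frame.notna().all().all()
        twice = impute_train(once, model)
        pd.testing.assert_frame_equal(twice.frame, once.frame)

    def test_derived_columns_consistent_after_imputation(self, small_cohort):
        enc = encode(small_cohort)
        model = fit_imputer(enc, FAST)
        out = impute_train(enc, model).frame
        np.testing.assert_allclose(
            out["map"], (out["systolic_pressure"] + 2 * out["diastolic_pressure"]) / 3
        )
        np.testing.assert_allclose(
            out["current_bmi"], out["current_weight"] / out["height"] ** 2
        )

    def test_imputed_independent_values_within_observed_range(self, small_cohort):
        enc = encode(small_cohort)
        model = fit_imputer(enc, FAST)
        out = impute_train(enc, model).frame
        pair_members = {m for _, a, b, _ in DEPENDENT_PAIRS for m in (a, b)}
        for feat in FEATURE_COLUMNS:
            if feat in pair_members or feat in DERIVED_COLUMNS:
                continue
            observed = enc.frame[feat].dropna()
            assert out[feat].min() >= observed.min() - 1e-12
            assert out[feat].max() <= observed.max() + 1e-12


class TestImputeTest:
    def test_overall_median_fill(self):
        spec = CohortSpec(n_cases=2, n_controls=3, missing_rate=0.0, seed=0)
        table = generate_cohort(spec)
        table.loc[table["label"] == "control", "age"] = [1.0, 2.0, 3.0]
        table.loc[table["label"] == "case", "age"] = [10.0, 20.0]
        enc = encode(table)
        model = fit_imputer(enc, FAST)
        test = enc.subset([0]).without_labels()
        test.frame.loc[0, "age"] = np.nan
        out = impute_test(test, model)
        assert out.frame.loc[0, "age"] == 3.0

    def test_complete_record_unchanged(self, complete_cohort):
        enc = encode(complete_cohort)
        model = fit_imputer(enc, FAST)
        out = impute_test(enc, model)
        pd.testing.assert_frame_equal(out.frame, enc.frame)

    def test_label_independence(self, small_cohort):
        enc = encode(small_cohort)
        model = fit_imputer(enc, ImputerConfig(min_pairs=10))
        with_labels = encode(small_cohort)
        without = encode(small_cohort).without_labels()
        a = impute_test(with_labels, model)
        b = impute_test(without, model)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_label_permutation_leaves_overall_medians(self, small_cohort):
        # metamorphic: permuting training labels must not change what
        # impute_test uses (overall medians over the pooled data)
        enc = encode(small_cohort)
        rng = np.random.default_rng(0)
        permuted = enc.copy()
        permuted.labels = pd.Series(rng.permutation(enc.labels.to_numpy()))
        m1 = fit_imputer(enc, FAST)
        m2 = fit_imputer(permuted, FAST)
        assert m1.overall_medians == m2.overall_medians
        test = enc.without_labels()
        pd.testing.assert_frame_equal(
            impute_test(test, m1).frame, impute_test(test, m2).frame
        )
        assert m1.intra_class_medians != m2.intra_class_medians

    def test_pooled_relation_recovery(self):
        # noiseless pairs: test-time relation imputation recovers the truth
        spec = CohortSpec(
            n_cases=60, n_controls=140, missing_rate=0.0, pair_noise_sd=0.0,
            bp_slope=1.0, bp_intercept=40.0, seed=4,
        )
        enc = encode(generate_cohort(spec))
        model = fit_imputer(enc, ImputerConfig(min_pairs=10))
        test = enc.subset(range(20)).without_labels()
        truth = test.frame["systolic_pressure"].to_numpy().copy()
        test.frame["systolic_pressure"] = np.nan
        out = impute_test(test, model)
        np.testing.assert_allclose(
            out.frame["systolic_pressure"].to_numpy(), truth, atol=5e-2
        )


def test_oracle_equivalence_full_pipeline_small_table():
    # every median-imputed cell equals an exhaustive recomputation
    spec = CohortSpec(n_cases=15, n_controls=35, missing_rate=0.3, seed=6)
    table = generate_cohort(spec)
    enc = encode(table)
    model = fit_imputer(enc, FAST)
    out = impute_train(enc, model).frame
    y = enc.labels.to_numpy()
    pair_members = {m for _, a, b, _ in DEPENDENT_PAIRS for m in (a, b)}
    for feat in FEATURE_COLUMNS:
        if feat in DERIVED_COLUMNS:
            continue
        col = enc.frame[feat]
        for i in np.flatnonzero(col.isna().to_numpy()):
            if feat in pair_members:
                _, a, b, _ = next(p for p in DEPENDENT_PAIRS if feat in (p[1], p[2]))
                partner = b if feat == a else a
                if not np.isnan(enc.frame.loc[i, partner]):
                    continue  # relation-imputed; not a median cell
            expected = brute_median(col[y == y[i]].tolist())
            if expected is None:
                expected = brute_median(col.tolist())
            assert out.loc[i, feat] == expected, (feat, i)
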