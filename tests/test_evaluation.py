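import itertools

import numpy as np
import pandas as pd
import pytest

from perisk.cohort import CohortSpec, generate_cohort
from perisk.encoding import encode
from perisk.evaluation import (
    augmented_real_test_cv,
    compute_metrics,
    early_enriched_cv,
    f1_from_counts,
    median_abs_deviation,
    median_low,
    repeated_cv,
    round_folds,
)
from perisk.imputation import ImputerConfig
from perisk.prediction import PredictorConfig

FAST_IMP = ImputerConfig(use_relations=False)
RF_FAST = PredictorConfig(hyperparameters={"n_estimators": 60})


def brute_force_auc(labels, scores):
    """Fraction of correctly ordered (case, control) pairs; ties count 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestMedianHelpers:
    def test_median_low_odd_and_even(self):
        assert median_low([3.0, 1.0, 2.0]) == 2.0
        assert median_low([4.0, 1.0, 2.0, 3.0]) == 2.0  # lower-middle

    def test_mad_zero_when_identical(self):
        assert median_abs_deviation([5.0, 5.0, 5.0]) == 0.0

    def test_mad_positive_on_spread_values(self):
        assert median_abs_deviation([1.0, 2.0]) > 0.0
        assert median_abs_deviation([1.0, 2.0, 3.0]) == 1.0


class TestComputeMetrics:
    def test_hand_computed_confusion(self):
        # tp=5, fn=5, fp=3, tn=7
        labels = [1] * 10 + [0] * 10
        scores = [0.9] * 5 + [0.1] * 5 + [0.9] * 3 + [0.1] * 7
        m = compute_metrics(labels, scores, threshold=0.5)
        assert (m.tp, m.fn, m.fp, m.tn) == (5, 5, 3, 7)
        assert m.tpr == pytest.approx(0.5)
        assert m.fpr == pytest.approx(0.3)
        assert m.error_rate == pytest.approx(0.4)
        assert m.f1 == pytest.approx(0.5556, abs=1e-4)

    def test_perfect_ranking(self):
        labels = [0, 0, 1, 1]
        scores = [0.1, 0.2, 0.8, 0.9]
        m = compute_metrics(labels, scores, threshold=0.5)
        assert m.auc_roc == 1.0
        assert m.auc_prc == 1.0

    def test_auc_equals_pairwise_ordering_fraction(self, rng):
        # brute-force oracle on <= 20 records
        labels = rng.integers(0, 2, 18)
        labels[:2] = [0, 1]
        scores = rng.random(18)
        m = compute_metrics(labels, scores, threshold=0.5)
        assert m.auc_roc == pytest.approx(brute_force_auc(labels, scores))

    def test_identities_hold_exactly(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 2, 30)
            labels[:2] = [0, 1]
            scores = rng.random(30)
            m = compute_metrics(labels, scores, threshold=rng.uniform(0.1, 0.9))
            assert m.tnr == 1.0 - m.fpr
            assert m.fnr == 1.0 - m.tpr
            assert m.tp + m.fp + m.tn + m.fn == 30
            p, r = m.precision, m.tpr
            expected_f1 = 2 * p * r / (p + r) if p + r else 0.0
            assert m.f1 == pytest.approx(expected_f1)

    def test_constant_score_degenerate_predictor(self):
        labels = [1] * 3 + [0] * 7
        scores = [0.3] * 10
        m = compute_metrics(labels, scores, threshold=0.5)
        assert m.tpr == 0.0 and m.fpr == 0.0
        assert m.error_rate == pytest.approx(0.3)  # case prevalence

    def test_single_class_aucs_nan_with_warning(self):
        with pytest.warns(UserWarning, match="single-class"):
            m = compute_metrics([1, 1, 1], [0.2, 0.5, 0.9], 0.5)
        assert np.isnan(m.auc_roc) and np.isnan(m.auc_prc)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [], 0.5)


class TestRoundFolds:
    def test_partition_disjoint_exhaustive_balanced(self, rng):
        y = np.array([1] * 20 + [0] * 60)
        splits = round_folds(y, 7, rng)
        all_test = np.concatenate([te for _, te in splits])
        assert sorted(all_test) == list(range(80))
        sizes = [len(te) for _, te in splits]
        assert max(sizes) - min(sizes) <= 1
        for tr, te in splits:
            assert set(tr) | set(te) == set(range(80))
            assert not set(tr) & set(te)
            assert len(np.unique(y[tr])) == 2

    def test_too_few_records_rejected(self, rng):
        with pytest.raises(ValueError):
            round_folds(np.array([0, 1]), 5, rng)


@pytest.fixture(scope="module")
def tiny_cohort():
    return generate_cohort(
        CohortSpec(n_cases=25, n_controls=55, missing_rate=0.2, seed=21)
    )


class TestRepeatedCV:
    def test_round_count_and_summary_oracle(self, tiny_cohort):
        res = repeated_cv(
            tiny_cohort, RF_FAST, rounds=3, folds=4, seed=0, imputer_config=FAST_IMP
        )
        assert len(res.per_round) == 3
        errs = [b.error_rate for b in res.per_round]
        assert res.summary()["error_rate"]["median"] == sorted(errs)[1]

    def test_single_round_median_is_value_deviation_zero(self, tiny_cohort):
        res = repeated_cv(
            tiny_cohort, RF_FAST, rounds=1, folds=4, seed=1, imputer_config=FAST_IMP
        )
        s = res.summary()
        assert s["f1"]["median"] == res.per_round[0].f1
        assert s["f1"]["deviation"] == 0.0
        # micro/macro collapse to plain f1 with a single round
        assert res.micro_f1() == pytest.approx(res.per_round[0].f1)
        assert res.macro_f1() == pytest.approx(res.per_round[0].f1)

    def test_deterministic_under_seed(self, tiny_cohort):
        a = repeated_cv(tiny_cohort, RF_FAST, rounds=2, folds=4, seed=3,
                        imputer_config=FAST_IMP)
        b = repeated_cv(tiny_cohort, RF_FAST, rounds=2, folds=4, seed=3,
                        imputer_config=FAST_IMP)
        assert [x.to_dict() for x in a.per_round] == [x.to_dict() for x in b.per_round]

    def test_requires_labels_and_enough_rows(self, tiny_cohort):
        with pytest.raises(ValueError):
            repeated_cv(tiny_cohort, RF_FAST, rounds=0)
        enc = encode(tiny_cohort).without_labels()
        with pytest.raises(ValueError):
            repeated_cv(enc, RF_FAST)

    def test_json_export(self, tiny_cohort, tmp_path):
        res = repeated_cv(tiny_cohort, RF_FAST, rounds=1, folds=4, seed=0,
                          imputer_config=FAST_IMP)
        res.to_json(tmp_path / "cv.json")
        import json

        loaded = json.loads((tmp_path / "cv.json").read_text())
        assert loaded["protocol"] == "standard"
        assert len(loaded["per_round"]) == 1


class TestEarlyEnrichedCV:
    def test_reduction_with_empty_non_early(self, tiny_cohort):
        a = early_enriched_cv(tiny_cohort, None, RF_FAST, rounds=2, folds=4,
                              seed=5, imputer_config=FAST_IMP)
        b = repeated_cv(tiny_cohort, RF_FAST, rounds=2, folds=4, seed=5,
                        imputer_config=FAST_IMP)
        assert [x.to_dict() for x in a.per_round] == [x.to_dict() for x in b.per_round]

    def test_folds_partition_only_early_set(self, rng):
        # protocol set identity, checked directly on the fold machinery
        y_early = np.array([1] * 10 + [0] * 20)
        extra = np.array([1] * 5 + [0] * 15)
        splits = round_folds(y_early, 5, rng, extra_labels=extra)
        union = np.concatenate([te for _, te in splits])
        assert sorted(union) == list(range(30))

    def test_runs_with_non_early_pool(self, tiny_cohort):
        non_early = generate_cohort(
            CohortSpec(n_cases=15, n_controls=45, missing_rate=0.2, seed=22,
                       gestational_day_range=(98, 237))
        )
        res = early_enriched_cv(tiny_cohort, non_early, RF_FAST, rounds=1,
                                folds=4, seed=0, imputer_config=FAST_IMP)
        assert res.protocol == "early_enriched"
        # test side is always the early set
        assert res.per_round[0].n == len(tiny_cohort)


def identity_augmenter(X, y):
    return X.copy(), y.copy(), np.array(["real"] * len(y), dtype=object)


def duplicate_augmenter(X, y):
    """Duplicate minority rows (flagged synthetic) up to the majority count."""
    minority = 1 if (y == 1).sum() < (y == 0).sum() else 0
    need = int((y != minority).sum() - (y == minority).sum())
    idx = np.resize(np.flatnonzero(y == minority), need)
    X2 = np.vstack([X, X[idx]])
    y2 = np.concatenate([y, y[idx]])
    origin = np.array(["real"] * len(y) + ["synthetic"] * need, dtype=object)
    return X2, y2, origin


class TestAugmentedRealTestCV:
    def test_identity_augmenter_gives_identical_results(self, tiny_cohort):
        on_all, on_real = augmented_real_test_cv(
            tiny_cohort, identity_augmenter, RF_FAST, rounds=2, folds=4,
            seed=2, imputer_config=FAST_IMP,
        )
        assert [a.to_dict() for a in on_all.per_round] == [
            r.to_dict() for r in on_real.per_round
        ]

    def test_real_only_metrics_cover_exactly_the_real_records(self, tiny_cohort):
        on_all, on_real = augmented_real_test_cv(
            tiny_cohort, duplicate_augmenter, RF_FAST, rounds=2, folds=4,
            seed=3, imputer_config=FAST_IMP,
        )
        for bundle in on_real.per_round:
            assert bundle.n == len(tiny_cohort)
        for bundle in on_all.per_round:
            assert bundle.n > len(tiny_cohort)

    def test_leakage_safe_variant_tests_on_real_only(self, tiny_cohort):
        on_all, on_real = augmented_real_test_cv(
            tiny_cohort, duplicate_augmenter, RF_FAST, rounds=1, folds=4,
            seed=4, imputer_config=FAST_IMP, augment_within_train=True,
        )
        assert [a.to_dict() for a in on_all.per_round] == [
            r.to_dict() for r in on_real.per_round
        ]
        assert on_all.per_round[0].n == len(tiny_cohort)
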