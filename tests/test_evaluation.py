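"""Forward-chaining CV, per-fold standardisation and the metric suite."""

import numpy as np
import pytest
from sklearn.model_selection import TimeSeriesSplit

from conftest import make_toy_labels, make_toy_plant
from phytoaffect.decoders import RidgeWindowDecoder
from phytoaffect.errors import DataError, DegenerateAnalysisError
from phytoaffect.evaluation import (
    balanced_accuracy,
    evaluate_pipeline,
    f1_scores,
    forward_chain_splits,
    majority_baseline,
    standardize_per_fold,
)
from phytoaffect.features import WindowSpec, make_windows


class TestForwardChainSplits:
    def test_twelve_samples_five_folds(self):
        plan = forward_chain_splits(12, 5)
        starts = [test[0] for _, test in plan]
        assert starts == [2, 4, 6, 8, 10]
        for train, test in plan:
            assert len(test) == 2
            np.testing.assert_array_equal(train, np.arange(test[0]))

    def test_no_temporal_leakage(self):
        for train, test in forward_chain_splits(103, 5):
            assert train.max() < test.min()

    def test_test_blocks_partition_tail(self):
        plan = forward_chain_splits(12, 5)
        tail = np.concatenate([test for _, test in plan])
        np.testing.assert_array_equal(tail, np.arange(2, 12))

    @pytest.mark.parametrize("n,k", [(12, 5), (100, 5), (57, 4), (219, 5)])
    def test_matches_sklearn_timeseries_split(self, n, k):
        ours = forward_chain_splits(n, k)
        theirs = list(TimeSeriesSplit(n_splits=k).split(np.zeros((n, 1))))
        for (tr_a, te_a), (tr_b, te_b) in zip(ours, theirs):
            np.testing.assert_array_equal(tr_a, tr_b)
            np.testing.assert_array_equal(te_a, te_b)

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError):
            forward_chain_splits(5, 5)


class TestStandardize:
    def test_train_mean_row_maps_to_zero(self):
        rng = np.random.default_rng(0)
        train = rng.standard_normal((50, 3)) * 4 + 2
        test = train.mean(axis=0, keepdims=True)
        train_Z, test_Z, _ = standardize_per_fold(train, test)
        np.testing.assert_allclose(test_Z, 0.0, atol=1e-10)
        np.testing.assert_allclose(train_Z.mean(0), 0.0, atol=1e-10)
        np.testing.assert_allclose(train_Z.std(0), 1.0, atol=1e-10)

    def test_constant_column_centred_not_scaled(self, caplog):
        train = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        with caplog.at_level("WARNING"):
            train_Z, _, _ = standardize_per_fold(train, train[:2])
        np.testing.assert_allclose(train_Z[:, 0], 0.0)
        assert any("constant" in r.message for r in caplog.records)

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(1)
        train = rng.standard_normal((40, 2))
        train_Z, _, _ = standardize_per_fold(train, train)
        again, _, _ = standardize_per_fold(train_Z, train_Z)
        np.testing.assert_allclose(again, train_Z, atol=1e-9)


class TestMetrics:
    def test_balanced_accuracy_on_binary_confusion(self):
        # pooled valence test matrix: recalls 67/78 and 71/102
        C = np.array([[67, 11], [31, 71]])
        assert abs(balanced_accuracy(C) - 0.7775) < 5e-4

    def test_perfect_diagonal_is_one(self):
        assert balanced_accuracy(np.diag([5, 9, 2])) == 1.0

    def test_one_sided_predictor_on_balanced_classes_is_half(self):
        assert balanced_accuracy(np.array([[50, 0], [50, 0]])) == 0.5

    def test_class_duplication_invariance(self):
        C = np.array([[40, 10], [20, 30]])
        C_dup = C.copy()
        C_dup[1] *= 7  # duplicate every class-1 sample 7x
        assert abs(balanced_accuracy(C) - balanced_accuracy(C_dup)) < 1e-12

    def test_f1_on_pooled_arousal_confusion(self):
        # positive class in the second row/column
        C = np.array([[656, 344], [546, 889]])
        f1, macro = f1_scores(C)
        assert abs(f1[1] - 0.666) < 5e-4

    def test_macro_f1_is_mean_of_binary_f1s(self):
        C = np.array([[30, 12], [7, 51]])
        f1, macro = f1_scores(C)
        assert abs(macro - f1.mean()) < 1e-12

    def test_never_predicted_class_gets_zero_f1(self):
        C = np.array([[10, 0], [5, 0]])
        f1, _ = f1_scores(C)
        assert f1[1] == 0.0

    def test_perfect_prediction_f1(self):
        f1, macro = f1_scores(np.diag([4, 4]))
        np.testing.assert_array_equal(f1, [1.0, 1.0])
        assert macro == 1.0

    def test_majority_baseline_printed_class_counts(self):
        assert round(majority_baseline([108, 111]), 2) == 0.51
        assert round(majority_baseline([1103, 1823]), 2) == 0.62
        assert majority_baseline([42]) == 1.0


def _separable_table(n=120, seed=0, flip=0.0):
    """Window table whose labels are a (possibly noisy) threshold of one
    feature; used as a decodability ceiling/floor harness."""
    rng = np.random.default_rng(seed)
    ts = np.arange(n) * 60.0
    v = (rng.random(n) > 0.5).astype(int)
    a = (rng.random(n) > 0.5).astype(int)
    plant = make_toy_plant(ts)
    labels = make_toy_labels(ts, v=v, a=a)
    table = make_windows(plant, labels, WindowSpec(1.0, 1.0))
    x_v = np.where(table.label_v > 0, 1.0, -1.0) + 0.1 * rng.standard_normal(len(table))
    x_a = np.where(table.label_a > 0, 1.0, -1.0) + 0.1 * rng.standard_normal(len(table))
    if flip:
        x_v = rng.standard_normal(len(table))
        x_a = rng.standard_normal(len(table))
    table.features = np.column_stack([x_v, x_a, rng.standard_normal(len(table))])
    table.feature_names = ["f_v", "f_a", "f_noise"]
    return table


class TestEvaluatePipeline:
    def test_separable_labels_reach_ceiling(self):
        table = _separable_table(seed=1)
        rep = evaluate_pipeline(table, RidgeWindowDecoder, target="v")
        assert rep.mean_balanced_accuracy > 0.95

    def test_independent_features_stay_near_chance(self):
        vals = []
        for seed in range(20):
            table = _separable_table(seed=seed, flip=1.0)
            rep = evaluate_pipeline(table, RidgeWindowDecoder, target="v")
            vals.append(rep.pooled_balanced_accuracy)
        assert 0.45 < np.mean(vals) < 0.55

    def test_deterministic_report(self):
        table = _separable_table(seed=2)
        r1 = evaluate_pipeline(table, RidgeWindowDecoder, target="q")
        r2 = evaluate_pipeline(table, RidgeWindowDecoder, target="q")
        assert r1.to_dict() == r2.to_dict()

    def test_pooled_confusion_counts_all_test_windows(self):
        table = _separable_table(seed=3)
        rep = evaluate_pipeline(table, RidgeWindowDecoder, target="v")
        n_test = sum(m["n_test"] for m in rep.fold_metrics)
        assert rep.pooled_confusion.sum() == n_test

    def test_quadrant_metrics_use_four_classes(self):
        table = _separable_table(seed=4)
        rep = evaluate_pipeline(table, RidgeWindowDecoder, target="q")
        assert rep.pooled_confusion.shape == (4, 4)
        assert rep.mean_balanced_accuracy > 0.9

    def test_single_class_overall_rejected(self):
        ts = np.arange(50) * 60.0
        plant = make_toy_plant(ts)
        labels = make_toy_labels(ts, v=np.ones(50, int), a=np.ones(50, int))
        table = make_windows(plant, labels, WindowSpec(1.0, 1.0))
        with pytest.raises(DegenerateAnalysisError):
            evaluate_pipeline(table, RidgeWindowDecoder, target="v")
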