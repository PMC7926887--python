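"""Metrics, scaling, classifier specs and the two cross-validation protocols."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, f1_score

import ecgmultirate as em
from ecgmultirate.evaluation import (
    ClassifierSpec,
    ConfusionMatrix,
    accuracy_from_confusion,
    auc_ovr,
    build_estimator,
    confusion,
    kappa_from_confusion,
    make_partial_blind_plan,
    micro_f1_from_confusion,
    minmax_scale,
    run_5cv,
    run_partial_blind,
)

LABELS = ("N", "RBBB", "APC", "LBBB")


def _labels_from_matrix(counts):
    """Expand a confusion matrix back into (y_true, y_pred) vectors."""
    y_true, y_pred = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            y_true.extend([i] * counts[i, j])
            y_pred.extend([j] * counts[i, j])
    return np.array(y_true), np.array(y_pred)


class TestMinMaxScale:
    def test_train_column_maps_to_unit_interval(self):
        train = np.array([[2.0], [4.0], [6.0]])
        scaled, _ = minmax_scale(train, train)
        np.testing.assert_allclose(scaled.ravel(), [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        train = np.full((3, 1), 5.0)
        scaled, test = minmax_scale(train, np.array([[7.0]]))
        assert np.all(scaled == 0.0)

    def test_test_values_outside_train_range_not_clipped(self):
        train = np.array([[0.0], [1.0]])
        _, test = minmax_scale(train, np.array([[2.0], [-1.0]]))
        np.testing.assert_allclose(test.ravel(), [2.0, -1.0])

    def test_feature_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            minmax_scale(np.zeros((2, 3)), np.zeros((2, 4)))


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array(["N", "APC", "N", "LBBB"])
        C = confusion(y, y, LABELS)
        assert np.trace(C.counts) == 4
        assert C.counts.sum() == 4

    def test_row_sums_are_class_counts(self, rng):
        y_true = rng.choice(LABELS, size=200)
        y_pred = rng.choice(LABELS, size=200)
        C = confusion(y_true, y_pred, LABELS)
        for i, lab in enumerate(LABELS):
            assert C.counts[i].sum() == np.sum(y_true == lab)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["N"], ["X"], LABELS)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(counts=np.array([[1, -1], [0, 1]]), labels=("a", "b"))


class TestMetricsAgainstSklearn:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kappa_and_micro_f1_match_reference(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 40, size=(4, 4))
        counts[np.diag_indices(4)] += 40
        C = ConfusionMatrix(counts=counts, labels=LABELS)
        y_true, y_pred = _labels_from_matrix(counts)
        assert kappa_from_confusion(C) == pytest.approx(
            100 * cohen_kappa_score(y_true, y_pred)
        )
        assert micro_f1_from_confusion(C) == pytest.approx(
            100 * f1_score(y_true, y_pred, average="micro")
        )
        assert accuracy_from_confusion(C) == pytest.approx(
            100 * np.mean(y_true == y_pred)
        )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_micro_f1_equals_accuracy_for_any_matrix(self, seed):
        counts = np.random.default_rng(seed).integers(0, 50, size=(4, 4))
        if counts.trace() == 0:
            counts[0, 0] = 1  # keep micro-precision defined
        C = ConfusionMatrix(counts=counts, labels=LABELS)
        assert micro_f1_from_confusion(C) == pytest.approx(accuracy_from_confusion(C))

    def test_perfect_matrix_metrics(self):
        C = ConfusionMatrix(counts=np.eye(4, dtype=int) * 10, labels=LABELS)
        assert accuracy_from_confusion(C) == 100.0
        assert kappa_from_confusion(C) == 100.0
        assert micro_f1_from_confusion(C) == 100.0

    def test_balanced_rows_give_quarter_chance_agreement(self, rng):
        """For equal row sums over 4 classes, pe = 1/4 exactly."""
        # build a matrix with equal row sums but arbitrary within-row split
        counts = np.zeros((4, 4), dtype=int)
        for i in range(4):
            row = rng.multinomial(100, np.ones(4) / 4)
            counts[i] = row
        C = ConfusionMatrix(counts=counts, labels=LABELS)
        total = counts.sum()
        pe_brute = sum(
            counts[i].sum() * counts[:, j].sum() / total**2
            for i, j in zip(range(4), range(4))
        )
        assert pe_brute == pytest.approx(0.25)
        p0 = counts.trace() / total
        assert kappa_from_confusion(C) == pytest.approx(100 * (p0 - 0.25) / 0.75)

    def test_degenerate_single_class_rejected(self):
        counts = np.zeros((2, 2), dtype=int)
        counts[0, 0] = 10
        with pytest.raises(ValueError, match="degenerate"):
            kappa_from_confusion(ConfusionMatrix(counts=counts, labels=("a", "b")))

    def test_empty_matrix_rejected(self):
        C = ConfusionMatrix(counts=np.zeros((2, 2), dtype=int), labels=("a", "b"))
        with pytest.raises(ValueError):
            accuracy_from_confusion(C)


class TestAuc:
    def test_perfect_separation(self):
        y = np.repeat(LABELS, 10)
        scores = np.zeros((40, 4))
        for i, lab in enumerate(LABELS):
            scores[np.asarray(y) == lab, i] = 1.0
        assert auc_ovr(scores, y, LABELS) == 100.0

    def test_uniform_random_scores_near_chance(self):
        rng = np.random.default_rng(7)
        y = rng.choice(LABELS, size=2000)
        scores = rng.dirichlet(np.ones(4), size=2000)
        assert auc_ovr(scores, y, LABELS) == pytest.approx(50.0, abs=3.0)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            auc_ovr(np.ones((3, 4)) / 4, ["N", "N", "APC"], LABELS)


class TestClassifierSpecs:
    def test_ann_width_switches_with_mode(self):
        assert ClassifierSpec.for_mode("ANN", "P1").ann_width == 90
        assert ClassifierSpec.for_mode("ANN", "P2").ann_width == 50

    def test_configured_hyperparameters(self):
        assert build_estimator(ClassifierSpec("KNN")).n_neighbors == 5
        svm = build_estimator(ClassifierSpec("SVM"))
        assert svm.kernel == "poly" and svm.degree == 3 and svm.C == 10.0
        assert build_estimator(ClassifierSpec("RF")).n_estimators == 100
        bag = build_estimator(ClassifierSpec("BAG"))
        assert bag.n_estimators == 10 and bag.estimator.kernel == "poly"
        ann = build_estimator(ClassifierSpec.for_mode("ANN", "P1"))
        assert ann.hidden_layer_sizes == (90, 90)
        dt = build_estimator(ClassifierSpec("DT"))
        assert dt.criterion == "gini" and dt.max_depth is None

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("XGB")


class TestFiveFold:
    def test_partition_and_determinism(self, features_p2):
        spec = ClassifierSpec.for_mode("DT", "P2", seed=0)
        res1 = run_5cv(features_p2, spec, seed=3)
        res2 = run_5cv(features_p2, spec, seed=3)
        assert len(res1.per_fold) == 5
        assert res1.aggregate_confusion.total == 2040
        assert np.array_equal(
            res1.aggregate_confusion.counts, res2.aggregate_confusion.counts
        )
        assert res1.per_fold == res2.per_fold
        assert res1.aggregate_accuracy == pytest.approx(
            100 * np.trace(res1.aggregate_confusion.counts) / 2040
        )

    def test_small_class_rejected(self):
        X = np.zeros((8, 32))
        fm = em.FeatureMatrix(
            X, ["N"] * 4 + ["APC"] * 4, ["s"] * 8, "P2"
        )
        fm.labels[-1] = "LBBB"  # a 1-member class
        with pytest.raises(ValueError, match=">= 5"):
            run_5cv(fm, ClassifierSpec("DT"))


class TestPartialBlind:
    def test_plan_structure_matches_printed_row_sums(self, features_p2):
        plan = make_partial_blind_plan(features_p2.subjects, features_p2.labels, 50, seed=0)
        assert len(plan.folds) == 3
        for f in plan.folds:
            assert len(f["test"]) == 4 * 120
            assert len(f["injected"]) == 4 * 50
            assert np.intersect1d(f["test"], f["injected"]).size == 0
            # injected rows train; tested rows never train in their own fold
            assert np.intersect1d(f["train"], f["test"]).size == 0
            assert np.all(np.isin(f["injected"], f["train"]))
        tested = np.concatenate([f["test"] for f in plan.folds])
        assert len(tested) == len(np.unique(tested)) == 1440
        per_class = {
            c: np.sum(features_p2.labels[tested] == c) for c in LABELS
        }
        assert all(v == 360 for v in per_class.values())

    def test_zero_injection_is_fully_blind(self, features_p2):
        plan = make_partial_blind_plan(features_p2.subjects, features_p2.labels, 0, seed=0)
        tested = np.concatenate([f["test"] for f in plan.folds])
        per_class = {c: np.sum(features_p2.labels[tested] == c) for c in LABELS}
        assert all(v == 510 for v in per_class.values())

    def test_oversized_injection_rejected(self, features_p2):
        with pytest.raises(ValueError, match="cell size"):
            make_partial_blind_plan(features_p2.subjects, features_p2.labels, 170)

    def test_unbalanced_subjects_rejected(self):
        subjects = np.array(["a", "a", "b", "b", "c", "c"])
        labels = np.array(["N", "N", "N", "N", "APC", "APC"])
        with pytest.raises(ValueError, match="subjects per class"):
            make_partial_blind_plan(subjects, labels, 1)

    def test_run_aggregates_tested_samples_only(self, features_p2):
        plan = make_partial_blind_plan(features_p2.subjects, features_p2.labels, 50, seed=0)
        res = run_partial_blind(features_p2, ClassifierSpec("DT", seed=0), plan)
        assert res.aggregate_confusion.total == 1440
        assert len(res.per_fold) == 3

    def test_fold_spread_reported(self, features_p2):
        """Subject-wise folds are more heterogeneous than random folds; the
        per-fold accuracy spread is reported (not asserted) for inspection."""
        plan = make_partial_blind_plan(features_p2.subjects, features_p2.labels, 50, seed=0)
        spec = ClassifierSpec("DT", seed=0)
        pb = run_partial_blind(features_p2, spec, plan)
        cv = run_5cv(features_p2, spec, seed=0)
        print(
            f"accuracy std: partial-blind {pb.mean_std['accuracy'][1]:.2f} "
            f"vs 5CV {cv.mean_std['accuracy'][1]:.2f}"
        )
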