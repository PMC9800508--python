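"""Splitting, training, confusion-matrix metrics and cross-validation."""

import numpy as np
import pytest
from sklearn import metrics as skm
from sklearn.base import BaseEstimator, ClassifierMixin

from mdls import classify as cl


def blobs(rng, n_per=50, margin=10.0, d=4, n_classes=3):
    X = np.concatenate(
        [rng.normal(loc=margin * k, scale=1.0, size=(n_per, d)) for k in range(n_classes)]
    )
    y = np.repeat(np.arange(n_classes), n_per)
    return X, y


class TestSplit:
    def test_ratio_and_partition(self, rng):
        X = rng.normal(size=(100, 5))
        y = np.array([0] * 34 + [1] * 33 + [2] * 33)
        X_tr, X_te, y_tr, y_te = cl.split_train_test(X, y, ratio=0.7, seed=0)
        assert abs(len(y_tr) - 70) <= 1 and abs(len(y_te) - 30) <= 1
        assert len(y_tr) + len(y_te) == 100
        # stratification: class proportions preserved within rounding
        for c in (0, 1, 2):
            assert abs((y_te == c).sum() - 10) <= 1

    def test_deterministic(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.repeat([0, 1, 2], 20)
        a = cl.split_train_test(X, y, seed=5)
        b = cl.split_train_test(X, y, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[3], b[3])

    def test_tiny_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0] * 9 + [1])
        with pytest.raises(ValueError):
            cl.split_train_test(X, y)


class TestTraining:
    @pytest.mark.parametrize("model", ["lr", "rf", "svm"])
    def test_separable_blobs_perfect_training_accuracy(self, model, rng):
        X, y = blobs(rng)
        est = cl.train_classifier(cl.ClassifierSpec(model=model, seed=0), X, y)
        assert np.mean(est.predict(X) == y) == 1.0

    def test_svm_defaults_carried(self):
        est = cl.build_estimator(cl.ClassifierSpec(model="svm"))
        svc = est[-1]
        assert svc.kernel == "linear"
        assert svc.C == 100.0
        assert svc.gamma == 0.0001
        assert svc.decision_function_shape == "ovr"
        assert svc.probability is True

    def test_constant_column_is_inert_under_standardization(self, rng):
        X, y = blobs(rng, d=3)
        spec = cl.ClassifierSpec(model="svm", seed=0)
        base = cl.train_classifier(spec, X, y)
        X_aug = np.column_stack([X, np.full(len(X), 7.0)])
        aug = cl.train_classifier(spec, X_aug, y)
        Xq, _ = blobs(rng, n_per=10, d=3)
        Xq_aug = np.column_stack([Xq, np.full(len(Xq), 7.0)])
        np.testing.assert_array_equal(base.predict(Xq), aug.predict(Xq_aug))

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            cl.train_classifier(cl.ClassifierSpec(model="lr"), X, np.zeros(20))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            cl.ClassifierSpec(model="mlp")
        with pytest.raises(ValueError):
            cl.ClassifierSpec(model="svm", hyperparameters={"C": -1.0})


class TestEvaluationReport:
    def test_binary_hand_example(self):
        """TP=2, FP=1, FN=1, TN=6 for the positive class: precision = recall
        = 2/3, F1 = 4/6, accuracy = 0.8."""
        y_true = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0])
        rep = cl.report_from_predictions(y_true, y_pred)
        pc = rep.per_class[1]
        assert (pc["tp"], pc["fp"], pc["fn"], pc["tn"]) == (2, 1, 1, 6)
        assert pc["precision"] == pytest.approx(2 / 3)
        assert pc["recall"] == pytest.approx(2 / 3)
        assert pc["f1"] == pytest.approx(4 / 6)
        assert pc["accuracy"] == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.8)

    def test_perfect_predictions(self):
        y = np.repeat([0, 1, 2], 5)
        rep = cl.report_from_predictions(y, y)
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0
        assert np.all(rep.confusion == np.diag([5, 5, 5]))

    def test_matches_sklearn_recount(self, rng):
        """Weighted metrics agree with an independent tally (scikit-learn)."""
        y_true = rng.integers(0, 3, size=200)
        y_pred = rng.integers(0, 3, size=200)
        rep = cl.report_from_predictions(y_true, y_pred, classes=np.arange(3))
        np.testing.assert_array_equal(
            rep.confusion, skm.confusion_matrix(y_true, y_pred, labels=[0, 1, 2])
        )
        assert rep.accuracy == pytest.approx(skm.accuracy_score(y_true, y_pred))
        p, r, f, _ = skm.precision_recall_fscore_support(
            y_true, y_pred, labels=[0, 1, 2], average="weighted", zero_division=0
        )
        assert rep.precision == pytest.approx(p)
        assert rep.recall == pytest.approx(r)
        assert rep.f1 == pytest.approx(f)

    def test_row_and_column_sums(self, rng):
        y_true = rng.integers(0, 3, size=120)
        y_pred = rng.integers(0, 3, size=120)
        rep = cl.report_from_predictions(y_true, y_pred, classes=np.arange(3))
        for c in range(3):
            assert rep.confusion[c].sum() == (y_true == c).sum()
            assert rep.confusion[:, c].sum() == (y_pred == c).sum()

    def test_binary_balanced_trace_equals_ovr_accuracy(self, rng):
        """In the binary case per-class one-vs-rest accuracy equals the
        overall trace/n accuracy; multi-class values are reported side by
        side instead of merged."""
        y_true = np.repeat([0, 1], 50)
        y_pred = rng.integers(0, 2, size=100)
        rep = cl.report_from_predictions(y_true, y_pred)
        assert rep.per_class[0]["accuracy"] == pytest.approx(rep.accuracy)
        assert rep.per_class[1]["accuracy"] == pytest.approx(rep.accuracy)

    def test_label_outside_classes_rejected(self):
        with pytest.raises(ValueError):
            cl.report_from_predictions(
                np.array([0, 3]), np.array([0, 0]), classes=np.arange(3)
            )

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            cl.report_from_predictions(np.array([]), np.array([]))


class _AlwaysZero(BaseEstimator, ClassifierMixin):
    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.zeros(len(X), dtype=int)


class TestCrossValidation:
    def test_degenerate_predictor_scores_one_third(self, rng):
        X = rng.normal(size=(90, 4))
        y = np.repeat([0, 1, 2], 30)
        mean, _, scores = cl.cross_validate(_AlwaysZero(), X, y, folds=5, seed=0)
        assert mean == pytest.approx(1.0 / 3.0, abs=1e-9)
        assert len(scores) == 5

    def test_folds_partition_indices(self, rng):
        from sklearn.model_selection import StratifiedKFold

        y = np.repeat([0, 1, 2], 20)
        skf = StratifiedKFold(5, shuffle=True, random_state=3)
        seen = []
        for _, te in skf.split(np.zeros((60, 1)), y):
            seen.extend(te.tolist())
        assert sorted(seen) == list(range(60))

    def test_cv_close_to_heldout_on_separable_data(self, rng):
        X, y = blobs(rng, n_per=40, margin=4.0)
        spec = cl.ClassifierSpec(model="lr", seed=0)
        mean, _, _ = cl.cross_validate(spec, X, y, folds=5, seed=0)
        X_tr, X_te, y_tr, y_te = cl.split_train_test(X, y, seed=0)
        est = cl.train_classifier(spec, X_tr, y_tr)
        heldout = cl.evaluate(est, X_te, y_te).accuracy
        assert abs(mean - heldout) <= 0.05

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            cl.cross_validate(_AlwaysZero(), np.zeros((3, 1)), np.array([0, 1, 2]), folds=5)
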