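"""SMOTE, one-vs-rest training protocol, and metric reporting."""

import numpy as np
import pytest

from dtilink.dataset import L6, make_cv_folds, one_hot
from dtilink.model import (
    MetricsReport,
    ModelBundle,
    TrainConfig,
    evaluate,
    smote_oversample,
    train_binary,
    train_one_vs_rest,
)

# fast protocol for unit tests: fewer, more aggressive boosting rounds
FAST = TrainConfig(
    n_estimators=60, learning_rate=0.3, early_stopping_rounds=10, depth_grid=(2, 3), seed=0
)


class TestSmote:
    def test_balanced_input_returned_unchanged(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([0] * 5 + [1] * 5)
        X2, y2 = smote_oversample(X, y, k=3, seed=0)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_counts_equalised(self, rng):
        X = rng.normal(size=(100, 4))
        y = np.array([1] * 20 + [0] * 80)
        X2, y2 = smote_oversample(X, y, k=5, seed=1)
        assert (y2 == 1).sum() == (y2 == 0).sum() == 80
        assert len(X2) == 160

    def test_synthetic_points_lie_on_minority_segment(self, rng):
        # minority at (0,0) and (1,1): every synthetic point must be (t, t)
        X = np.vstack([[0.0, 0.0], [1.0, 1.0], rng.normal(10, 0.1, size=(8, 2))])
        y = np.array([1, 1] + [0] * 8)
        X2, y2 = smote_oversample(X, y, k=1, seed=2)
        synthetic = X2[len(X):]
        assert len(synthetic) == 6
        for pt in synthetic:
            assert pt[0] == pytest.approx(pt[1], abs=1e-12)
            assert 0.0 <= pt[0] <= 1.0

    def test_originals_preserved_bitwise(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.array([1] * 5 + [0] * 25)
        digest = X.tobytes()
        X2, _ = smote_oversample(X, y, k=3, seed=3)
        assert X2[:30].tobytes() == digest

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            smote_oversample(rng.normal(size=(5, 2)), np.ones(5), k=1, seed=0)

    def test_k_reduced_with_warning_when_minority_small(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([1] * 3 + [0] * 17)
        with pytest.warns(UserWarning, match="reducing k"):
            X2, y2 = smote_oversample(X, y, k=5, seed=0)
        assert (y2 == 1).sum() == 17


def separable_features(rng, n_per_label=30):
    """Six separable clusters, one per label; single-label rows.

    Feature j is an exact 0/10 indicator of label j (noise only on the
    two trailing dimensions), so no test point can fall inside the
    decision margin.
    """
    X, Y = [], []
    for j in range(6):
        block = np.zeros((n_per_label, 8))
        block[:, j] = 10.0
        block[:, 6:] = rng.normal(scale=0.3, size=(n_per_label, 2))
        X.append(block)
        Y.append(np.tile(one_hot({L6[j]}), (n_per_label, 1)))
    return np.vstack(X), np.vstack(Y)


class TestTrainOneVsRest:
    def test_six_models_on_six_label_data(self, rng):
        X, Y = separable_features(rng)
        folds = make_cv_folds(len(X), k=5, repeats=1, seed=0)[0]
        models, depths, scores = train_one_vs_rest(X, Y, folds, FAST)
        assert sum(m is not None for m in models.values()) == 6
        assert set(depths) == set(L6)

    def test_separable_labels_reach_perfect_validation_f1(self, rng):
        X, Y = separable_features(rng)
        folds = make_cv_folds(len(X), k=5, repeats=1, seed=0)[0]
        _, _, scores = train_one_vs_rest(X, Y, folds, FAST)
        for lab in L6:
            assert max(scores[lab].values()) == pytest.approx(1.0)

    def test_same_data_and_seed_select_same_depths(self, rng):
        X, Y = separable_features(rng, n_per_label=15)
        folds = make_cv_folds(len(X), k=5, repeats=1, seed=1)[0]
        _, d1, _ = train_one_vs_rest(X, Y, folds, FAST)
        _, d2, _ = train_one_vs_rest(X, Y, folds, FAST)
        assert d1 == d2

    def test_absent_label_marked_untrainable(self, rng):
        X, Y = separable_features(rng, n_per_label=10)
        Y = Y.copy()
        Y[:, 5] = 0  # erase the last label entirely
        folds = make_cv_folds(len(X), k=5, repeats=1, seed=0)[0]
        with pytest.warns(UserWarning, match="lacks two training samples"):
            models, _, _ = train_one_vs_rest(X, Y, folds, FAST)
        assert models[L6[5]] is None
        assert sum(m is not None for m in models.values()) == 5


class TestTrainBinary:
    def test_separable_classes_classified_perfectly(self, rng):
        pos = rng.normal(5, 0.3, size=(40, 4))
        neg = rng.normal(-5, 0.3, size=(40, 4))
        folds = make_cv_folds(80, k=5, repeats=1, seed=0)[0]
        clf, depth, _ = train_binary(pos, neg, folds, FAST)
        X_test = np.vstack([rng.normal(5, 0.3, size=(20, 4)), rng.normal(-5, 0.3, size=(20, 4))])
        y_test = np.array([1] * 20 + [0] * 20)
        pred = (clf.predict_proba(X_test)[:, 1] >= 0.5).astype(int)
        assert (pred == y_test).mean() == 1.0

    def test_identical_distributions_score_near_chance(self, rng):
        pos = rng.normal(size=(60, 4))
        neg = rng.normal(size=(60, 4))
        folds = make_cv_folds(120, k=5, repeats=1, seed=0)[0]
        clf, _, _ = train_binary(pos, neg, folds, FAST)
        X_test = rng.normal(size=(400, 4))
        y_test = np.array([1] * 200 + [0] * 200)
        acc = ((clf.predict_proba(X_test)[:, 1] >= 0.5).astype(int) == y_test).mean()
        assert abs(acc - 0.5) < 0.15  # within sampling error of chance

    def test_probabilities_bounded(self, rng):
        pos = rng.normal(2, 1, size=(30, 3))
        neg = rng.normal(-2, 1, size=(30, 3))
        folds = make_cv_folds(60, k=5, repeats=1, seed=0)[0]
        clf, _, _ = train_binary(pos, neg, folds, FAST)
        probs = clf.predict_proba(rng.normal(size=(50, 3)))[:, 1]
        assert np.all((probs >= 0) & (probs <= 1))

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_binary(rng.normal(size=(5, 2)), np.empty((0, 2)), [], FAST)


class _StubClassifier:
    """Deterministic probability table keyed by row index."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        p = self.probs[: len(X)]
        return np.column_stack([1 - p, p])


def stub_bundle(label_probs, binary_probs):
    return ModelBundle(
        label_models={lab: _StubClassifier(label_probs[j]) for j, lab in enumerate(L6)},
        binary_model=_StubClassifier(binary_probs),
        depths={lab: 3 for lab in L6},
        binary_depth=3,
        config=TrainConfig(),
    )


class TestEvaluate:
    def test_precision_from_confusion_counts(self):
        # label 0: predictions on 8 rows -> TP=3, FP=1 -> precision 0.75
        y_true = np.zeros((8, 6), dtype=int)
        y_true[:3, 0] = 1  # 3 true positives among 4 predicted
        probs = [[0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1]] + [[0.0] * 8] * 5
        with pytest.warns(UserWarning):
            report = evaluate(stub_bundle(probs, [0.5] * 8), np.zeros((8, 2)), y_true)
        assert report.per_label[L6[0]]["precision"] == pytest.approx(0.75)

    def test_perfect_predictions_score_one_everywhere(self):
        y_true = np.zeros((6, 6), dtype=int)
        probs = []
        for j in range(6):
            y_true[j, j] = 1
            probs.append([1.0 if i == j else 0.0 for i in range(6)])
        report = evaluate(stub_bundle(probs, [1.0] * 6), np.zeros((6, 2)), y_true)
        for lab in L6:
            assert report.per_label[lab] == {"accuracy": 1.0, "f1": 1.0, "precision": 1.0}
        assert report.macro["precision"] == 1.0

    def test_inverted_predictions_on_balanced_set_score_zero_accuracy(self):
        y_true = np.zeros((4, 6), dtype=int)
        y_true[:2, 0] = 1
        probs = [[0.1, 0.1, 0.9, 0.9]] + [[0.0] * 4] * 5
        with pytest.warns(UserWarning):
            report = evaluate(stub_bundle(probs, [0.5] * 4), np.zeros((4, 2)), y_true)
        assert report.per_label[L6[0]]["accuracy"] == 0.0

    def test_f1_identity_with_precision_and_recall(self, rng):
        y_true = np.zeros((40, 6), dtype=int)
        y_true[:, 0] = rng.integers(0, 2, size=40)
        p = rng.random(40)
        probs = [p.tolist()] + [[0.0] * 40] * 5
        with pytest.warns(UserWarning):
            report = evaluate(stub_bundle(probs, [0.5] * 40), np.zeros((40, 2)), y_true)
        from sklearn.metrics import recall_score

        pred = (p >= 0.5).astype(int)
        prec = report.per_label[L6[0]]["precision"]
        rec = recall_score(y_true[:, 0], pred, zero_division=0)
        if prec + rec > 0:
            assert report.per_label[L6[0]]["f1"] == pytest.approx(
                2 * prec * rec / (prec + rec)
            )

    def test_macro_row_is_unweighted_mean(self):
        y_true = np.zeros((6, 6), dtype=int)
        y_true[0, :] = 1
        probs = [[0.9] * 6, [0.1] * 6, [0.9] * 6, [0.1] * 6, [0.9] * 6, [0.1] * 6]
        with pytest.warns(UserWarning):
            report = evaluate(stub_bundle(probs, [0.5] * 6), np.zeros((6, 2)), y_true)
        accs = [report.per_label[lab]["accuracy"] for lab in L6]
        assert report.macro["accuracy"] == pytest.approx(np.mean(accs))


class TestMetricsReport:
    def _report(self, value):
        return MetricsReport(
            per_label={lab: {"accuracy": value, "f1": value, "precision": value} for lab in L6},
            binary={"accuracy": value, "f1": value, "precision": value},
        )

    def test_aggregate_mean_and_variance(self):
        agg = MetricsReport.aggregate([self._report(0.4), self._report(0.6)])
        assert agg.loc["Total", "precision"] == pytest.approx(0.5)
        assert agg.loc["Total", "precision_var"] == pytest.approx(0.01)

    def test_tsv_round_trip_layout(self, tmp_path):
        path = tmp_path / "metrics.tsv"
        self._report(0.75).to_tsv(path)
        lines = path.read_text().strip().split("\n")
        assert lines[0].startswith("label\t")
        assert any(ln.startswith("Total\t") for ln in lines)
        assert any(ln.startswith("Binary") for ln in lines)
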