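"""SVM evaluation: fold stratification, standardisation statistics,
kernel capacity, metric definitions against an exhaustive-count oracle,
and chance/separable CV limits."""

import numpy as np
import pytest

from cascadix.evaluation import (
    SVMConfig,
    StratificationError,
    cross_validate,
    make_svm,
    metrics_from_predictions,
    standardize,
    stratified_kfold,
    train_svm,
)
from cascadix.synthetic import generate_separable_features


def oracle_metrics(y_true, y_pred):
    """Independent metric oracle: literal one-vs-rest counting per class."""
    classes = sorted(set(y_true) | set(y_pred))
    n = len(y_true)
    per_class = {}
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        tn = n - tp - fp - fn
        per_class[c] = {
            "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
            "accuracy": (tp + tn) / n,
        }
    macro = {
        m: float(np.mean([per_class[c][m] for c in classes]))
        for m in ("sensitivity", "specificity", "precision", "f1")
    }
    macro["accuracy"] = sum(1 for t, p in zip(y_true, y_pred) if t == p) / n
    return macro, per_class


class TestStratifiedKFold:
    def test_exactly_divisible_case(self):
        labels = np.repeat([f"c{i}" for i in range(10)], 10)
        folds = stratified_kfold(labels, k=5, seed=0)
        assert all(len(f) == 20 for f in folds)
        for f in folds:
            _, counts = np.unique(labels[f], return_counts=True)
            assert (counts == 2).all()

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["a", "b", "c"], size=47, p=[0.5, 0.3, 0.2])
        labels = np.concatenate([labels, ["a", "b", "c"] * 5])  # ensure >= k members
        folds = stratified_kfold(labels, k=5, seed=1)
        allidx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(allidx, np.arange(len(labels)))
        for i in range(len(folds)):
            for j in range(i + 1, len(folds)):
                assert len(np.intersect1d(folds[i], folds[j])) == 0

    def test_per_class_counts_differ_by_at_most_one(self):
        labels = np.repeat(["a", "b", "c"], [17, 23, 11])
        folds = stratified_kfold(labels, k=5, seed=2)
        for cls in "abc":
            counts = [np.sum(labels[f] == cls) for f in folds]
            assert max(counts) - min(counts) <= 1

    def test_small_class_rejected(self):
        labels = np.array(["a"] * 20 + ["b"] * 3)
        with pytest.raises(StratificationError):
            stratified_kfold(labels, k=5)


class TestStandardize:
    def test_hand_computed_statistics(self):
        train = np.array([[1.0], [3.0]])
        test = np.array([[5.0]])
        tr, te = standardize(train, test)
        np.testing.assert_allclose(tr, [[-1.0], [1.0]])  # population sd = 1
        np.testing.assert_allclose(te, [[3.0]])  # (5 - 2) / 1

    def test_constant_columns_map_to_zero(self):
        train = np.full((4, 2), 7.0)
        tr, te = standardize(train, train)
        np.testing.assert_allclose(tr, 0.0)
        np.testing.assert_allclose(te, 0.0)


class TestTrainSVM:
    def test_separable_data_fits_exactly(self):
        fm = generate_separable_features(10, 4, 3, separation=10.0, seed=1)
        for kernel in ("linear", "cubic"):
            model = train_svm(fm.values, fm.labels, kernel)
            assert (model.predict(fm.values) == fm.labels).mean() == 1.0

    def test_quadratic_kernel_solves_xor_where_linear_cannot(self):
        rng = np.random.default_rng(8)
        centers = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        X = np.vstack([c + 0.15 * rng.standard_normal((30, 2)) for c in centers])
        y = np.array(["pos"] * 60 + ["neg"] * 60)
        linear = train_svm(X, y, "linear").predict(X)
        quadratic = train_svm(X, y, "quadratic").predict(X)
        assert (linear == y).mean() <= 0.75
        assert (quadratic == y).mean() >= 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((5, 2)), np.array(["a"] * 5))

    def test_kernel_config_mapping(self):
        assert SVMConfig("linear").degree == 1
        assert SVMConfig("quadratic").degree == 2
        assert SVMConfig("cubic").degree == 3
        assert SVMConfig("linear").effective_coef0 == 0.0
        assert SVMConfig("cubic").effective_coef0 == 1.0
        with pytest.raises(ValueError):
            make_svm("rbf")


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array(["a", "b", "c", "a"])
        _, m = metrics_from_predictions(y, y)
        for key in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
            assert m[key] == 1.0

    def test_hand_derived_binary_example(self):
        y_true = np.array(["A", "A", "B", "B"])
        y_pred = np.array(["A", "B", "B", "B"])
        counts, m = metrics_from_predictions(y_true, y_pred)
        a = m["per_class"]["A"]
        b = m["per_class"]["B"]
        assert (a["sensitivity"], a["specificity"], a["precision"]) == (0.5, 1.0, 1.0)
        assert np.isclose(a["f1"], 2 / 3)
        assert (b["sensitivity"], b["specificity"]) == (1.0, 0.5)
        assert np.isclose(b["precision"], 2 / 3) and np.isclose(b["f1"], 0.8)
        assert m["accuracy"] == 0.75

    def test_all_one_class_predictions_give_half_macro_sensitivity(self):
        y_true = np.array(["x"] * 10 + ["y"] * 10)
        y_pred = np.array(["x"] * 20)
        _, m = metrics_from_predictions(y_true, y_pred)
        assert m["sensitivity"] == 0.5
        assert m["degenerate"]  # precision of the never-predicted class is 0/0

    def test_matches_exhaustive_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = rng.integers(2, 5)
            n = rng.integers(4, 30)
            y_true = rng.integers(0, k, n).astype(str)
            y_pred = rng.integers(0, k, n).astype(str)
            _, m = metrics_from_predictions(y_true, y_pred)
            macro, per_class = oracle_metrics(list(y_true), list(y_pred))
            for key, val in macro.items():
                assert np.isclose(m[key], val), key
            for c, ref in per_class.items():
                for key, val in ref.items():
                    assert np.isclose(m["per_class"][c][key], val), (c, key)

    def test_f1_is_harmonic_mean_where_defined(self):
        rng = np.random.default_rng(7)
        y_true = rng.integers(0, 3, 60).astype(str)
        y_pred = rng.integers(0, 3, 60).astype(str)
        _, m = metrics_from_predictions(y_true, y_pred)
        for c, d in m["per_class"].items():
            p, s = d["precision"], d["sensitivity"]
            if p > 0 and s > 0:
                assert np.isclose(d["f1"], 2 * p * s / (p + s))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_predictions(np.array(["a"]), np.array(["a", "b"]))


class TestCrossValidate:
    def test_separable_limit_all_kernels(self):
        fm = generate_separable_features(10, 5, 3, separation=10.0, seed=2)
        reports = cross_validate(fm.values, fm.labels, seed=1)
        assert set(reports) == {"linear", "quadratic", "cubic"}
        for rep in reports.values():
            assert rep.mean() == 1.0
            assert len(rep.folds) == 5

    def test_permuted_labels_are_chance_level(self):
        rng = np.random.default_rng(0)
        fm = generate_separable_features(30, 8, 8, separation=5.0, seed=3)
        labels = rng.permutation(fm.labels)
        rep = cross_validate(fm.values, labels, ["linear"], seed=4)["linear"]
        p = 1 / 8
        se = np.sqrt(p * (1 - p) / fm.n_samples)
        assert abs(rep.mean() - p) <= 3 * se

    def test_same_seed_gives_identical_report(self):
        fm = generate_separable_features(8, 4, 4, separation=1.0, seed=5)
        a = cross_validate(fm.values, fm.labels, ["quadratic"], seed=9)["quadratic"]
        b = cross_validate(fm.values, fm.labels, ["quadratic"], seed=9)["quadratic"]
        assert [f.as_dict() for f in a.folds] == [f.as_dict() for f in b.folds]

    def test_all_metrics_bounded(self):
        fm = generate_separable_features(8, 4, 4, separation=1.0, seed=6)
        for rep in cross_validate(fm.values, fm.labels, seed=2).values():
            for fold in rep.folds:
                for v in fold.as_dict().values():
                    assert 0.0 <= v <= 1.0
            assert np.isclose(rep.mean_metrics.accuracy, np.mean([f.accuracy for f in rep.folds]))
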