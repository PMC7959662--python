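"""Multi-kernel SVM training, stratified 5-fold CV and the five metrics.

The classifier stage trains one-vs-one polynomial-kernel SVMs,
K(x, y) = (gamma <x, y> + c0)^p with p = 1 (linear), 2 (quadratic) or
3 (cubic), on per-fold standardised features.  Metrics are the usual
one-vs-rest confusion quantities per class — sensitivity TP/(TP+FN),
specificity TN/(TN+FP), precision TP/(TP+FP), F1 2TP/(2TP+FP+FN) — macro
averaged, with the headline accuracy being overall correct/n (the
per-class (TP+TN)/n variant is also reported in the detail block, since
the two differ for more than two classes).

Folds are stratified and, crucially, reused across kernels and feature
sets within a run so that comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datatypes import CVReport, FoldMetrics

__all__ = [
    "SVMConfig",
    "KERNEL_DEGREES",
    "stratified_kfold",
    "standardize",
    "train_svm",
    "make_svm",
    "metrics_from_predictions",
    "cross_validate",
]

KERNEL_DEGREES = {"linear": 1, "quadratic": 2, "cubic": 3}


class StratificationError(ValueError):
    pass


@dataclass(frozen=True)
class SVMConfig:
    """Polynomial-kernel SVM parameters.

    gamma defaults to the 'scale' heuristic 1 / (d * mean feature
    variance); c0 defaults to 0 for the linear kernel and 1 for the
    curved ones.  Multiclass handling is libsvm's one-vs-one voting.
    """

    kernel: str = "linear"
    C: float = 1.0
    gamma: float | str = "scale"
    coef0: float | None = None

    def validate(self) -> None:
        if self.kernel not in KERNEL_DEGREES:
            raise ValueError(
                f"kernel must be one of {sorted(KERNEL_DEGREES)}, got {self.kernel!r}"
            )

    @property
    def degree(self) -> int:
        return KERNEL_DEGREES[self.kernel]

    @property
    def effective_coef0(self) -> float:
        if self.coef0 is not None:
            return self.coef0
        return 0.0 if self.kernel == "linear" else 1.0


def make_svm(cfg: SVMConfig | str, standardize: bool = True) -> Pipeline:
    """Pipeline(StandardScaler, SVC) realising the configured kernel."""
    if isinstance(cfg, str):
        cfg = SVMConfig(kernel=cfg)
    cfg.validate()
    svc = SVC(
        kernel="poly",
        degree=cfg.degree,
        gamma=cfg.gamma,
        coef0=cfg.effective_coef0,
        C=cfg.C,
        cache_size=500,
    )
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", svc))
    return Pipeline(steps)


def train_svm(X: np.ndarray, y: np.ndarray, cfg: SVMConfig | str = "linear") -> Pipeline:
    """Fit an SVM on (X, y); deterministic given inputs and config."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return make_svm(cfg).fit(np.asarray(X, dtype=np.float64), y)


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """k disjoint stratified test-index folds covering all samples.

    Per-class counts across folds differ by at most one; a class with
    fewer than k members cannot be stratified and is an error.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} members; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def standardize(train: np.ndarray, apply_to: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardise with the training statistics only.

    Population standard deviation; constant columns map to zero.
    """
    scaler = StandardScaler().fit(np.asarray(train, dtype=np.float64))
    return scaler.transform(train), scaler.transform(np.asarray(apply_to, dtype=np.float64))


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class."""

    classes: list
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])


def _safe_div(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, bool]:
    """Elementwise num/den with 0 where den == 0, flagging the degeneracy."""
    den = np.asarray(den, dtype=np.float64)
    out = np.divide(num, den, out=np.zeros_like(den), where=den > 0)
    return out, bool((den == 0).any())


def metrics_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[ConfusionCounts, dict]:
    """Confusion counts and the five metrics (macro + per class).

    The headline ``accuracy`` is overall correct/n.  Per-class values,
    including the one-vs-rest (TP+TN)/n accuracy variant, live under
    ``per_class``.  Zero-denominator rates are reported as 0 and flagged
    via ``degenerate``.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    classes = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    n = len(y_true)
    tp = np.array([np.sum((y_true == c) & (y_pred == c)) for c in classes])
    fp = np.array([np.sum((y_true != c) & (y_pred == c)) for c in classes])
    fn = np.array([np.sum((y_true == c) & (y_pred != c)) for c in classes])
    tn = n - tp - fp - fn
    counts = ConfusionCounts(classes, tp, tn, fp, fn)

    sens, d1 = _safe_div(tp, tp + fn)
    spec, d2 = _safe_div(tn, tn + fp)
    prec, d3 = _safe_div(tp, tp + fp)
    f1, d4 = _safe_div(2 * tp, 2 * tp + fp + fn)
    per_class_acc = (tp + tn) / n
    metrics = {
        "accuracy": float(np.mean(y_true == y_pred)),
        "sensitivity": float(sens.mean()),
        "specificity": float(spec.mean()),
        "precision": float(prec.mean()),
        "f1": float(f1.mean()),
        "degenerate": d1 or d2 or d3 or d4,
        "per_class": {
            c: {
                "accuracy": float(per_class_acc[i]),
                "sensitivity": float(sens[i]),
                "specificity": float(spec[i]),
                "precision": float(prec[i]),
                "f1": float(f1[i]),
                "tp": int(tp[i]),
                "tn": int(tn[i]),
                "fp": int(fp[i]),
                "fn": int(fn[i]),
            }
            for i, c in enumerate(classes)
        },
    }
    return counts, metrics


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    kernels: list[str] | None = None,
    k: int = 5,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
    feature_set: str = "features",
    standardize_folds: bool = True,
) -> dict[str, CVReport]:
    """Per-fold standardise -> train -> predict -> score, for each kernel.

    Pass precomputed ``folds`` to pair comparisons across feature sets;
    otherwise folds are derived from (labels, seed) and therefore equal
    for equal label vectors.
    """
    X = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    kernels = kernels or list(KERNEL_DEGREES)
    if folds is None:
        folds = stratified_kfold(labels, k=k, seed=seed)
    all_idx = np.arange(len(labels))
    reports: dict[str, CVReport] = {}
    for kernel in kernels:
        fold_metrics: list[FoldMetrics] = []
        last_per_class: dict = {}
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            model = make_svm(kernel, standardize=standardize_folds)
            model.fit(X[train_idx], labels[train_idx])
            pred = model.predict(X[test_idx])
            _, m = metrics_from_predictions(labels[test_idx], pred)
            fold_metrics.append(
                FoldMetrics(
                    m["accuracy"], m["sensitivity"], m["specificity"], m["precision"], m["f1"]
                )
            )
            last_per_class = m["per_class"]
        reports[kernel] = CVReport(
            feature_set=feature_set,
            kernel=kernel,
            folds=fold_metrics,
            seed=seed,
            per_class=last_per_class,
        )
    return reports
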