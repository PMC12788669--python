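"""Cross-validation protocol and multiclass metrics.

The outer loop is stratified 5-fold cross-validation (each fold serves once
as the test set); inside each training fold the trainer takes its own 10%
validation holdout for early stopping.  Metrics are accuracy and macro- and
weighted-averaged precision/recall/F1 from the 6x6 confusion matrix; macro
is the headline averaging and weighted is also reported since the two
coincide only on balanced labels.  Zero-support classes contribute 0 to the
macro averages (with a warning from the metrics backend suppressed by
``zero_division=0``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .models import TrainedModel, predict

N_CLASSES = 6


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of: np.ndarray  # sample index -> fold index
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


@dataclass
class MetricsReport:
    accuracy: float
    f1: float
    recall: float
    precision: float
    f1_weighted: float
    recall_weighted: float
    precision_weighted: float
    per_class: dict = field(default_factory=dict)
    confusion: np.ndarray | None = None

    def as_row(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "recall": self.recall,
            "precision": self.precision,
        }


def make_folds(labels: Sequence[int], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified partition of the index set into k folds of near-equal size.

    Folds are disjoint and exhaustive; the same seed reproduces the same
    assignment.  Raises for n < k or a single class.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("stratified folds need at least 2 classes")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(n, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
        fold_of[test_idx] = fold
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)


def compute_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    n_classes: int = N_CLASSES,
) -> MetricsReport:
    """Confusion-matrix metrics with macro (headline) and weighted averages."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    class_range = np.arange(n_classes)
    cm = confusion_matrix(y_true, y_pred, labels=class_range)
    accuracy = float(np.trace(cm) / cm.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f, support = precision_recall_fscore_support(
            y_true, y_pred, labels=class_range, zero_division=0
        )
        pm, rm, fm, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=class_range, average="macro", zero_division=0
        )
        pw, rw, fw, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=class_range, average="weighted", zero_division=0
        )
    per_class = {
        int(c): {"precision": float(p[i]), "recall": float(r[i]),
                 "f1": float(f[i]), "support": int(support[i])}
        for i, c in enumerate(class_range)
    }
    return MetricsReport(
        accuracy=accuracy,
        f1=float(fm), recall=float(rm), precision=float(pm),
        f1_weighted=float(fw), recall_weighted=float(rw), precision_weighted=float(pw),
        per_class=per_class,
        confusion=cm,
    )


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    fold_accuracies: list[float]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def min_accuracy(self) -> float:
        return float(np.min(self.fold_accuracies))

    @property
    def max_accuracy(self) -> float:
        return float(np.max(self.fold_accuracies))

    def mean_metric(self, name: str) -> float:
        return float(np.mean([getattr(r, name) for r in self.fold_reports]))


def run_cv(
    inputs,
    labels: Sequence[int],
    fit_predict: Callable[[object, np.ndarray, np.ndarray, np.ndarray], np.ndarray] | None = None,
    model_factory: Callable[[], object] | None = None,
    folds: FoldAssignment | None = None,
    k: int = 5,
    seed: int = 0,
    n_classes: int = N_CLASSES,
) -> CVResult:
    """Cross-validate a model over ``folds``.

    ``inputs`` is a single array or a tuple of aligned arrays (first axis =
    samples).  ``model_factory`` builds a fresh model handle per fold;
    ``fit_predict(model, train_idx, test_idx, labels)`` trains on the train
    indices and returns test-fold predictions.  Leakage is asserted
    structurally: train and test index sets must be disjoint and the test
    sets must partition the dataset.
    """
    labels = np.asarray(labels)
    folds = folds or make_folds(labels, k=k, seed=seed)
    seen_test: list[np.ndarray] = []
    reports: list[MetricsReport] = []
    for fold in range(folds.k):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        assert len(np.intersect1d(tr, te)) == 0, "train/test leakage"
        seen_test.append(te)
        model = model_factory() if model_factory is not None else None
        y_pred = fit_predict(model, tr, te, labels)
        reports.append(compute_metrics(labels[te], y_pred, n_classes=n_classes))
    all_test = np.sort(np.concatenate(seen_test))
    assert np.array_equal(all_test, np.arange(len(labels))), "folds must partition"
    return CVResult(fold_reports=reports, fold_accuracies=[r.accuracy for r in reports])


def subset_inputs(inputs, idx: np.ndarray):
    if isinstance(inputs, tuple):
        return tuple(a[idx] for a in inputs)
    return inputs[idx]


def nn_fit_predict(spec, inputs, train_cfg):
    """fit_predict closure for the numpy network models."""
    from .models import train_model

    def _run(_model, tr, te, labels):
        fitted = train_model(spec, subset_inputs(inputs, tr), labels[tr], train_cfg)
        y_pred, _ = predict(fitted, subset_inputs(inputs, te))
        return y_pred

    return _run


def svm_fit_predict(vectors, svm_cfg=None):
    """fit_predict closure for the linear SVM baseline."""
    from .models import train_svm

    def _run(_model, tr, te, labels):
        fitted = train_svm(vectors[tr], labels[tr], svm_cfg)
        y_pred, _ = predict(fitted, vectors[te])
        return y_pred

    return _run
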