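"""Cross-validated multiclass evaluation: accuracy, macro F1, confusion.

The multiclass problem is scored one-vs-rest: an F1 score is computed
per class and the unweighted mean is the macro F1.  Cross-validation is
stratified by class and seeded; the confusion matrix is accumulated over
held-out folds only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from pancnv._seeds import derive_seed
from pancnv.matrix import CNVMatrix

logger = logging.getLogger(__name__)


class Classifier(Protocol):
    """Contract shared by the SNN and random-forest classifiers."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Classifier": ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...


#: a factory maps a seed to a fresh, unfitted classifier
ClassifierFactory = Callable[[int], Classifier]


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """c x c counts, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    return np.bincount(
        y_true * n_classes + y_pred, minlength=n_classes * n_classes
    ).reshape(n_classes, n_classes)


def accuracy(confusion) -> float:
    """Fraction correct: trace over total."""
    conf = np.asarray(confusion, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = conf.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(conf) / total)


def per_class_f1(confusion) -> np.ndarray:
    """One-vs-rest F1 per class; a class with no true and no predicted
    positives contributes 0 (with a logged warning)."""
    conf = np.asarray(confusion, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = np.diag(conf)
    denom = conf.sum(axis=0) + conf.sum(axis=1)  # predicted + true positives
    zero = denom == 0
    if zero.any():
        logger.warning(
            "class(es) %s have no true or predicted samples; F1 set to 0",
            np.flatnonzero(zero).tolist(),
        )
    with np.errstate(invalid="ignore"):
        f1 = np.where(zero, 0.0, 2.0 * tp / np.where(zero, 1.0, denom))
    return f1


def macro_f1(confusion) -> float:
    """Unweighted mean of the per-class one-vs-rest F1 scores."""
    return float(per_class_f1(confusion).mean())


@dataclass
class EvaluationReport:
    confusion: np.ndarray
    accuracy: float
    per_class_f1: np.ndarray
    macro_f1: float
    fold_assignments: np.ndarray
    seed: int
    class_names: list[str]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class_f1": {
                name: float(f)
                for name, f in zip(self.class_names, self.per_class_f1)
            },
            "confusion": self.confusion.tolist(),
            "class_names": self.class_names,
            "seed": self.seed,
        }


def cross_validate(
    matrix: CNVMatrix,
    feature_subset: Sequence[str] | np.ndarray,
    classifier_factory: ClassifierFactory,
    folds: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of a classifier on a feature subset.

    ``feature_subset`` is a list of feature IDs (or column indices).  A
    fresh classifier is built per fold with a fold-derived seed; the
    confusion matrix pools held-out predictions from every fold.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = matrix.labels
    counts = np.bincount(y, minlength=matrix.n_classes)
    if counts.min() < folds:
        k = int(np.argmin(counts))
        raise ValueError(
            f"class {matrix.class_names[k]!r} has {counts[k]} samples, "
            f"fewer than {folds} folds"
        )
    if len(feature_subset) == 0:
        raise ValueError("feature subset is empty")
    if isinstance(feature_subset[0], str):
        cols = matrix.columns(list(feature_subset))
    else:
        cols = np.asarray(feature_subset, dtype=np.int64)
    X = matrix.values[:, cols]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
    fold_assignments = np.empty(matrix.n_samples, dtype=np.int64)
    conf = np.zeros((matrix.n_classes, matrix.n_classes), dtype=np.int64)
    for fold, (train, test) in enumerate(skf.split(X, y)):
        fold_assignments[test] = fold
        clf = classifier_factory(derive_seed(seed, "fold", fold))
        clf.fit(X[train], y[train])
        pred = np.asarray(clf.predict(X[test]))
        conf += confusion_matrix(y[test], pred, matrix.n_classes)

    return EvaluationReport(
        confusion=conf,
        accuracy=accuracy(conf),
        per_class_f1=per_class_f1(conf),
        macro_f1=macro_f1(conf),
        fold_assignments=fold_assignments,
        seed=seed,
        class_names=list(matrix.class_names),
    )
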