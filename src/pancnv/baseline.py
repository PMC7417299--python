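"""Random-forest baseline classifier.

A thin wrapper over scikit-learn's ``RandomForestClassifier`` exposing
the same fit/predict contract as the SNN classifier, so it plugs into
incremental feature selection and cross-validation unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from pancnv.matrix import CNVMatrix


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class RFClassifier:
    def __init__(self, config: RFConfig | None = None):
        self.config = config or RFConfig()
        self._rf = RandomForestClassifier(
            n_estimators=self.config.n_trees,
            max_features=self.config.max_features,
            max_depth=self.config.max_depth,
            random_state=self.config.seed % (2**32),
            n_jobs=1,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RFClassifier":
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        self._rf.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        # re-expand to the full class range in case a class was absent
        raw = self._rf.predict_proba(np.asarray(X, dtype=float))
        classes = self._rf.classes_.astype(int)
        n_classes = int(classes.max()) + 1
        probs = np.zeros((raw.shape[0], n_classes))
        probs[:, classes] = raw
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._rf.predict(np.asarray(X, dtype=float)).astype(np.int64)


def rf_factory(config: RFConfig | None = None):
    """Classifier factory: maps a seed to a fresh random forest."""
    base = config or RFConfig()

    def make(seed: int) -> RFClassifier:
        return RFClassifier(replace(base, seed=seed))

    return make


@dataclass
class RFModel:
    """Trained forest bound to its feature subset; same predict contract
    as the SNN model."""

    classifier: RFClassifier
    feature_ids: list[str]
    class_names: list[str]
    config: RFConfig

    def predict(self, matrix: CNVMatrix) -> tuple[np.ndarray, np.ndarray]:
        cols = matrix.columns(self.feature_ids)
        probs = self.classifier.predict_proba(matrix.values[:, cols])
        return np.argmax(probs, axis=1), probs


def train_rf(
    matrix: CNVMatrix, feature_subset: Sequence[str], config: RFConfig | None = None
) -> RFModel:
    config = config or RFConfig()
    if len(feature_subset) == 0:
        raise ValueError("feature subset is empty")
    cols = matrix.columns(list(feature_subset))
    clf = RFClassifier(config)
    clf.fit(matrix.values[:, cols], matrix.labels)
    return RFModel(
        classifier=clf,
        feature_ids=list(feature_subset),
        class_names=list(matrix.class_names),
        config=config,
    )
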