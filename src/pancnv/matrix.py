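"""The in-memory CNV cohort container.

A cohort is a samples x features table of discrete copy-number states
(GISTIC thresholded convention by default: -2 deep loss, -1 shallow loss,
0 neutral, +1 gain, +2 amplification) together with per-sample class
labels (tumour types).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_STATES: tuple[int, ...] = (-2, -1, 0, 1, 2)


class CNVMatrixError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class CNVMatrix:
    """Samples x features table of discrete CNV states with class labels.

    Parameters
    ----------
    values
        Integer array of shape ``(n_samples, n_features)``; every entry
        must be one of ``state_values``.
    sample_ids, feature_ids
        Unique identifiers for rows and columns.
    labels
        Per-sample class index in ``[0, n_classes)``.
    class_names
        Names of the classes, indexed by label.
    state_values
        The declared, ordered (ascending) discrete state set.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    labels: np.ndarray
    class_names: list[str]
    state_values: tuple[int, ...] = DEFAULT_STATES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise CNVMatrixError(
                f"{len(self.sample_ids)} sample IDs for {n} rows"
            )
        if len(self.feature_ids) != m:
            raise CNVMatrixError(
                f"{len(self.feature_ids)} feature IDs for {m} columns"
            )
        if len(set(self.feature_ids)) != m:
            raise CNVMatrixError("feature IDs are not unique")
        if len(set(self.sample_ids)) != n:
            raise CNVMatrixError("sample IDs are not unique")
        if self.labels.shape != (n,):
            raise CNVMatrixError(
                f"label count {self.labels.shape[0]} != sample count {n}"
            )
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise CNVMatrixError("labels outside [0, n_classes)")
        states = np.asarray(self.state_values)
        if not np.isin(self.values, states).all():
            bad = np.argwhere(~np.isin(self.values, states))[0]
            i, j = int(bad[0]), int(bad[1])
            raise CNVMatrixError(
                f"value {self.values[i, j]} at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r} is outside the state set "
                f"{tuple(self.state_values)}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def state_indices(self) -> np.ndarray:
        """Values recoded as indices into ``state_values`` (ordinal 0..S-1)."""
        states = np.asarray(self.state_values)
        # searchsorted is exact because validate() guarantees membership
        return np.searchsorted(states, self.values).astype(np.int64)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self._feature_lookup[feature_id]
        except AttributeError:
            self._feature_lookup = {f: i for i, f in enumerate(self.feature_ids)}
            return self._feature_lookup[feature_id]

    def columns(self, feature_ids: list[str]) -> np.ndarray:
        """Column indices for a list of feature IDs; raises on unknown IDs."""
        missing = [f for f in feature_ids if f not in set(self.feature_ids)]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:10]}")
        return np.asarray([self.feature_index(f) for f in feature_ids])
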