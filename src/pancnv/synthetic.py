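"""Synthetic GISTIC-style CNV cohorts with planted class-informative features.

Real input to the pipeline is a thresholded copy-number table (discrete
states per gene per tumour sample) plus tumour-type labels.  This module
generates cohorts of the same shape with a known ground truth: most
features are class-independent categorical noise, while a small planted
set has its state distribution shifted toward a gain or loss tail in
exactly one class.  Ranking and classification stages can then be scored
against the planted set without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from pancnv.matrix import CNVMatrix, DEFAULT_STATES

#: Class-independent state distribution for noise features: most mass on
#: the neutral state, symmetric shallow/deep tails.
DEFAULT_NOISE_PROBS: tuple[float, ...] = (0.05, 0.15, 0.60, 0.15, 0.05)


class CohortConfigError(ValueError):
    """Invalid cohort specification; the message names the offending field."""


class PlantedFeature(NamedTuple):
    """Ground truth for one informative feature."""

    feature_id: str
    column: int
    class_index: int
    direction: int  # +1: mass shifted toward the gain tail, -1: loss tail


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``effect_strength`` is the fraction of the neutral-state probability
    mass moved to the designated tail state for an informative feature in
    its designated class; 0 makes planted features indistinguishable from
    noise, 1 moves all neutral mass to the tail.
    """

    n_per_class: tuple[int, ...] = (518, 597, 372, 597)
    n_features: int = 23109
    n_informative_per_class: int = 50
    state_values: tuple[int, ...] = DEFAULT_STATES
    noise_probs: tuple[float, ...] = DEFAULT_NOISE_PROBS
    effect_strength: float = 0.5
    seed: int = 0
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.n_per_class) < 2:
            raise CohortConfigError("n_per_class: need at least 2 classes")
        if any(int(n) <= 0 for n in self.n_per_class):
            raise CohortConfigError("n_per_class: all counts must be positive")
        if self.n_features <= 0:
            raise CohortConfigError("n_features: must be positive")
        if self.n_informative_per_class < 0:
            raise CohortConfigError("n_informative_per_class: must be >= 0")
        if self.n_informative_per_class * len(self.n_per_class) > self.n_features:
            raise CohortConfigError(
                "n_informative_per_class: planted features "
                f"({self.n_informative_per_class} x {len(self.n_per_class)} classes) "
                f"exceed n_features ({self.n_features})"
            )
        if not 0.0 <= self.effect_strength <= 1.0:
            raise CohortConfigError("effect_strength: must lie in [0, 1]")
        if len(self.noise_probs) != len(self.state_values):
            raise CohortConfigError(
                "noise_probs: length must match state_values"
            )
        if not math.isclose(sum(self.noise_probs), 1.0, abs_tol=1e-9):
            raise CohortConfigError("noise_probs: must sum to 1")
        if list(self.state_values) != sorted(set(self.state_values)):
            raise CohortConfigError(
                "state_values: must be strictly increasing"
            )
        if self.class_names is not None and len(self.class_names) != len(self.n_per_class):
            raise CohortConfigError(
                "class_names: length must match n_per_class"
            )

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_class))


def _informative_probs(spec: CohortSpec, direction: int) -> np.ndarray:
    """Noise distribution with ``effect_strength`` of the neutral mass
    moved to the extreme state of the chosen tail."""
    p = np.asarray(spec.noise_probs, dtype=float).copy()
    neutral = int(np.argmax(p))
    tail = len(p) - 1 if direction > 0 else 0
    shift = spec.effect_strength * p[neutral]
    p[neutral] -= shift
    p[tail] += shift
    return p


def generate_cohort(spec: CohortSpec) -> tuple[CNVMatrix, list[PlantedFeature]]:
    """Generate a cohort plus the ground-truth planted feature set.

    Noise features are iid draws from ``spec.noise_probs`` over the state
    set.  Planted feature columns are chosen uniformly at random (seeded),
    assigned to classes round-robin in column order, with gain/loss tail
    direction alternating; within the designated class the column is
    redrawn from the shifted distribution.  Identical spec + seed gives a
    byte-identical matrix.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, c = spec.n_samples, spec.n_features, spec.n_classes
    states = np.asarray(spec.state_values, dtype=np.int8)

    labels = np.repeat(np.arange(c), np.asarray(spec.n_per_class, dtype=int))
    state_idx = rng.choice(len(states), size=(n, m), p=np.asarray(spec.noise_probs))

    n_planted = spec.n_informative_per_class * c
    planted_cols = np.sort(rng.choice(m, size=n_planted, replace=False))

    width = max(5, len(str(m)))
    feature_ids = [f"G{j + 1:0{width}d}" for j in range(m)]
    swidth = max(4, len(str(n)))
    sample_ids = [f"S{i + 1:0{swidth}d}" for i in range(n)]
    if spec.class_names is not None:
        class_names = list(spec.class_names)
    else:
        class_names = [f"C{k + 1}" for k in range(c)]

    planted: list[PlantedFeature] = []
    for order, col in enumerate(planted_cols):
        klass = order % c
        direction = 1 if (order // c) % 2 == 0 else -1
        probs = _informative_probs(spec, direction)
        rows = np.flatnonzero(labels == klass)
        state_idx[rows, col] = rng.choice(len(states), size=rows.size, p=probs)
        planted.append(
            PlantedFeature(feature_ids[col], int(col), klass, direction)
        )

    matrix = CNVMatrix(
        values=states[state_idx],
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        labels=labels,
        class_names=class_names,
        state_values=spec.state_values,
    )
    return matrix, planted


def paper_scale_preset() -> CohortSpec:
    """Cohort dimensions of the original four-cancer TCGA study: 2,084
    samples (518 LUAD, 597 OV, 372 LIHC, 597 BRCA) x 23,109 features."""
    return CohortSpec(
        n_per_class=(518, 597, 372, 597),
        n_features=23109,
        n_informative_per_class=50,
        effect_strength=0.5,
        class_names=("LUAD", "OV", "LIHC", "BRCA"),
        seed=0,
    )


def desk_preset(seed: int = 0) -> CohortSpec:
    """Small cohort for end-to-end runs on one CPU: 4 classes x 100
    samples, 2,000 features, 40 planted, strong effect."""
    return CohortSpec(
        n_per_class=(100, 100, 100, 100),
        n_features=2000,
        n_informative_per_class=10,
        effect_strength=0.8,
        seed=seed,
    )


def write_planted(planted: list[PlantedFeature], path) -> None:
    """Write the planted feature IDs one per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in planted:
            fh.write(p.feature_id + "\n")
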