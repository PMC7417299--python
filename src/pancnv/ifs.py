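"""Incremental Feature Selection (IFS).

Given a ranked feature list, IFS evaluates a classifier by stratified
cross-validation on nested prefixes of the ranking (the i-th subset
holds the first ``i*k`` features), producing a curve of
(n_features, accuracy, macro F1) points from which the best prefix
length is selected.  A two-stage variant first scans coarsely with step
``k``, derives a fine interval around the coarse optimum, then scans
every size in that interval.

Each prefix's cross-validation seed is derived from the global seed and
the prefix size alone, so curve points are independent of evaluation
order and a size evaluated in both stages gets identical metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pancnv._seeds import derive_seed
from pancnv.evaluation import ClassifierFactory, cross_validate
from pancnv.io import RankedFeatures
from pancnv.matrix import CNVMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IFSConfig:
    """IFS scan parameters.

    ``fine_interval`` is a (lo, hi) pair of prefix sizes or ``"auto"``,
    in which case the interval runs from the smallest coarse prefix
    whose accuracy is within 1% (relative) of the coarse maximum through
    the coarse argmax prefix.  ``fine_stride`` thins the fine scan for
    desk-scale runs (1 = every integer size).
    """

    k: int = 10
    coarse_max: int = 5000
    fine_interval: tuple[int, int] | str = "auto"
    fine_stride: int = 1
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.coarse_max < self.k:
            raise ValueError("coarse_max must be >= k")
        if self.fine_stride < 1:
            raise ValueError("fine_stride must be >= 1")
        if isinstance(self.fine_interval, str):
            if self.fine_interval != "auto":
                raise ValueError("fine_interval must be (lo, hi) or 'auto'")
        else:
            lo, hi = self.fine_interval
            if lo > hi or lo < 1:
                raise ValueError("fine_interval must satisfy 1 <= lo <= hi")


@dataclass
class IFSCurve:
    """Ordered (n_features, accuracy, macro_f1) points plus the optimum."""

    points: list[tuple[int, float, float]]
    best_n: int
    best_metrics: tuple[float, float]

    def __post_init__(self) -> None:
        sizes = [p[0] for p in self.points]
        if sizes != sorted(set(sizes)):
            raise ValueError("curve sizes must be strictly increasing")


def select_best(points: "IFSCurve | Sequence[tuple[int, float, float]]"):
    """Best prefix: highest accuracy, ties broken toward higher macro F1,
    then toward the smallest feature count."""
    if isinstance(points, IFSCurve):
        points = points.points
    if not points:
        raise ValueError("empty IFS curve")
    best = max(points, key=lambda p: (p[1], p[2], -p[0]))
    return best[0], (best[1], best[2])


def _curve(points: list[tuple[int, float, float]]) -> IFSCurve:
    best_n, best_metrics = select_best(points)
    return IFSCurve(points=points, best_n=best_n, best_metrics=best_metrics)


def ifs_scan(
    ranked: RankedFeatures,
    matrix: CNVMatrix,
    classifier_factory: ClassifierFactory,
    config: IFSConfig | None = None,
    sizes: Sequence[int] | None = None,
) -> IFSCurve:
    """Cross-validate the classifier on each ranking prefix.

    ``sizes`` defaults to the coarse grid ``k, 2k, ..., coarse_max``;
    sizes beyond the number of ranked features are truncated with a
    warning.
    """
    config = config or IFSConfig()
    M = len(ranked)
    if sizes is None:
        sizes = list(range(config.k, config.coarse_max + 1, config.k))
    sizes = sorted(set(int(s) for s in sizes))
    if sizes and sizes[-1] > M:
        logger.warning(
            "prefix sizes beyond the %d ranked features are truncated", M
        )
        sizes = [s for s in sizes if s <= M]
    if not sizes:
        raise ValueError("no valid prefix sizes to scan")

    points: list[tuple[int, float, float]] = []
    for size in sizes:
        report = cross_validate(
            matrix,
            ranked.top(size),
            classifier_factory,
            folds=config.cv_folds,
            seed=derive_seed(config.seed, "ifs", size),
        )
        points.append((size, report.accuracy, report.macro_f1))
        logger.info(
            "IFS prefix %d: accuracy %.4f, macro F1 %.4f",
            size, report.accuracy, report.macro_f1,
        )
    return _curve(points)


def auto_fine_interval(coarse: IFSCurve, rel_tol: float = 0.01) -> tuple[int, int]:
    """Plateau-onset interval: from the smallest prefix within
    ``rel_tol`` (relative) of the coarse maximum accuracy through the
    coarse optimum's prefix."""
    max_acc = max(p[1] for p in coarse.points)
    lo = min(p[0] for p in coarse.points if p[1] >= (1.0 - rel_tol) * max_acc)
    return lo, coarse.best_n


def two_stage_scan(
    ranked: RankedFeatures,
    matrix: CNVMatrix,
    classifier_factory: ClassifierFactory,
    config: IFSConfig | None = None,
) -> tuple[IFSCurve, IFSCurve, tuple[int, tuple[float, float]]]:
    """Coarse scan, then a fine scan of the interval around the optimum.

    Returns (coarse curve, fine curve, overall best) where the overall
    best is selected over the union of both curves' points.
    """
    config = config or IFSConfig()
    coarse = ifs_scan(ranked, matrix, classifier_factory, config)
    if config.fine_interval == "auto":
        lo, hi = auto_fine_interval(coarse)
    else:
        lo, hi = config.fine_interval
    hi = min(hi, len(ranked))
    fine_sizes = sorted(set(range(lo, hi + 1, config.fine_stride)) | {hi})
    logger.info("fine IFS interval [%d, %d], %d sizes", lo, hi, len(fine_sizes))
    fine = ifs_scan(ranked, matrix, classifier_factory, config, sizes=fine_sizes)

    merged = {p[0]: p for p in coarse.points}
    merged.update({p[0]: p for p in fine.points})
    best = select_best(sorted(merged.values()))
    return coarse, fine, best
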