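"""Readers and writers for every on-disk artifact of the pipeline.

All text artifacts are UTF-8, tab- or comma-separated with Unix newlines
and no timestamps, so identical inputs produce byte-identical files.
Readers validate and reject rather than silently coerce.

Formats
-------
matrix TSV
    Header row of feature IDs; first column ``sample_id``; samples in
    rows, features in columns (the transpose of GISTIC's genes x samples
    orientation).
labels TSV
    Two columns ``sample_id``, ``class_name``, with header.
ranking TSV
    Columns ``rank``, ``feature_id``, ``ri``; RI written via ``repr`` so
    a re-read reproduces the in-memory float bit-for-bit.
IFS curve CSV
    Columns ``n_features``, ``accuracy``, ``macro_f1``.
confusion CSV
    Class names as header row and first column; rows = true class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pancnv.matrix import CNVMatrix, DEFAULT_STATES


class ParseError(ValueError):
    """A file failed validation; the message carries coordinates."""


# ---------------------------------------------------------------------------
# ranked features
# ---------------------------------------------------------------------------

@dataclass
class RankedFeatures:
    """Feature IDs ordered by non-increasing relative importance.

    Ties in RI are broken lexicographically by feature ID, so a ranking
    is a deterministic function of the scores.
    """

    feature_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.feature_ids) != self.scores.shape[0]:
            raise ValueError("feature_ids and scores lengths differ")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs in ranking")
        if self.scores.size and self.scores.min() < 0:
            raise ValueError("RI scores must be non-negative")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("RI scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def top(self, n: int) -> list[str]:
        return self.feature_ids[:n]

    @staticmethod
    def from_scores(feature_ids: list[str], scores: np.ndarray) -> "RankedFeatures":
        """Sort features by RI descending, ties by feature ID ascending."""
        scores = np.asarray(scores, dtype=float)
        order = sorted(range(len(feature_ids)), key=lambda i: (-scores[i], feature_ids[i]))
        return RankedFeatures(
            [feature_ids[i] for i in order], scores[order]
        )


# ---------------------------------------------------------------------------
# matrix + labels
# ---------------------------------------------------------------------------

def write_matrix(matrix: CNVMatrix, path, labels_path) -> None:
    """Write the cohort as a matrix TSV and a labels TSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\t" + "\t".join(matrix.feature_ids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            row = "\t".join(str(int(v)) for v in matrix.values[i])
            fh.write(f"{sid}\t{row}\n")
    with open(labels_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tclass_name\n")
        for sid, lab in zip(matrix.sample_ids, matrix.labels):
            fh.write(f"{sid}\t{matrix.class_names[lab]}\n")


def read_matrix(path, labels_path, state_values: tuple[int, ...] = DEFAULT_STATES) -> CNVMatrix:
    """Read a matrix TSV + labels TSV into a validated :class:`CNVMatrix`.

    Raises :class:`ParseError` naming the offending cell for values
    outside ``state_values``, and listing samples whose label is missing.
    Class order is the order of first appearance in the labels file.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sample_id":
        raise ParseError(
            f"{path}: malformed header, first column must be 'sample_id' "
            f"(got {df.columns[0]!r})"
        )
    feature_ids = list(df.columns[1:])
    sample_ids = df.iloc[:, 0].tolist()
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-integer matrix value ({exc})") from exc

    states = np.asarray(state_values)
    bad = ~np.isin(values, states)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ParseError(
            f"{path}: value {values[i, j]} at sample {sample_ids[i]!r}, "
            f"feature {feature_ids[j]!r} (row {i + 2}, column {j + 2}) is "
            f"outside the state set {tuple(state_values)}"
        )

    lab = pd.read_csv(labels_path, sep="\t", dtype=str)
    if list(lab.columns) != ["sample_id", "class_name"]:
        raise ParseError(
            f"{labels_path}: malformed header, expected "
            f"'sample_id\\tclass_name' (got {list(lab.columns)})"
        )
    label_of = dict(zip(lab["sample_id"], lab["class_name"]))
    missing = [s for s in sample_ids if s not in label_of]
    if missing:
        raise ParseError(
            f"{labels_path}: no label for sample(s) {missing[:10]}"
        )
    extra = [s for s in label_of if s not in set(sample_ids)]
    if extra:
        raise ParseError(
            f"{labels_path}: label(s) for unknown sample(s) {extra[:10]}"
        )

    class_names: list[str] = []
    for name in lab["class_name"]:
        if name not in class_names:
            class_names.append(name)
    class_index = {name: k for k, name in enumerate(class_names)}
    labels = np.asarray([class_index[label_of[s]] for s in sample_ids])

    return CNVMatrix(
        values=values,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        labels=labels,
        class_names=class_names,
        state_values=tuple(state_values),
    )


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def write_ranking(ranked: RankedFeatures, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rank\tfeature_id\tri\n")
        for r, (fid, ri) in enumerate(zip(ranked.feature_ids, ranked.scores), start=1):
            fh.write(f"{r}\t{fid}\t{float(ri)!r}\n")


def read_ranking(path) -> RankedFeatures:
    df = pd.read_csv(
        path, sep="\t", dtype={"feature_id": str}, float_precision="round_trip"
    )
    if list(df.columns) != ["rank", "feature_id", "ri"]:
        raise ParseError(
            f"{path}: malformed header, expected 'rank\\tfeature_id\\tri'"
        )
    if df["feature_id"].duplicated().any():
        dup = df["feature_id"][df["feature_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate feature ID {dup!r}")
    return RankedFeatures(df["feature_id"].tolist(), df["ri"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# IFS curve + confusion matrix
# ---------------------------------------------------------------------------

def write_curve(points: list[tuple[int, float, float]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("n_features,accuracy,macro_f1\n")
        for n, acc, f1 in points:
            fh.write(f"{int(n)},{float(acc)!r},{float(f1)!r}\n")


def read_curve(path) -> list[tuple[int, float, float]]:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["n_features", "accuracy", "macro_f1"]:
        raise ParseError(f"{path}: malformed IFS curve header")
    return [
        (int(n), float(a), float(f))
        for n, a, f in df.itertuples(index=False)
    ]


def write_confusion(confusion: np.ndarray, class_names: list[str], path) -> None:
    confusion = np.asarray(confusion)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("true\\pred," + ",".join(class_names) + "\n")
        for name, row in zip(class_names, confusion):
            fh.write(name + "," + ",".join(str(int(v)) for v in row) + "\n")


def read_confusion(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.int64), list(df.columns)
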