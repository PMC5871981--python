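"""Similarity-cutoff nested training-set construction.

The benchmark design: given a train x test protein-similarity matrix and an
ascending cutoff schedule, a training complex is retained at cutoff c when
no test complex is more similar than c to it, i.e. when

    max_j S[i, j] <= c.

A single above-cutoff test complex is enough to remove a training complex.
Ties at the cutoff are retained (closed boundary).  Because the rule is
monotone in c, the retained sets are nested: a larger cutoff keeps a
superset of any smaller cutoff, which is exactly the "nested training set"
construction used in similarity-debiasing studies of scoring functions.

How the similarity values were computed (sequence identity, structural
alignment score, ...) is opaque to this module; the matrix is an input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityMatrix",
    "CutoffSchedule",
    "NestedPartition",
    "max_test_similarity",
    "build_nested_sets",
    "partition_report",
    "percent_of_total",
]


class SimilarityMatrix:
    """Train-id x test-id protein similarity values in [0, 1]."""

    def __init__(self, frame: pd.DataFrame):
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("similarity matrix contains non-finite values")
        if values.size and (values.min() < 0 or values.max() > 1):
            raise ValueError("similarity values must lie in [0, 1]")
        if frame.index.has_duplicates or frame.columns.has_duplicates:
            raise ValueError("duplicate train or test ids")
        self.frame = frame

    @property
    def train_ids(self) -> list:
        return list(self.frame.index)

    @property
    def test_ids(self) -> list:
        return list(self.frame.columns)

    def row_max(self) -> pd.Series:
        """Per-training-complex maximum similarity to any test complex."""
        return self.frame.max(axis=1)

    def drop_test_column(self, test_id) -> "SimilarityMatrix":
        return SimilarityMatrix(self.frame.drop(columns=[test_id]))

    @classmethod
    def from_csv(cls, stream) -> "SimilarityMatrix":
        if isinstance(stream, str) and "\n" in stream:
            stream = io.StringIO(stream)
        frame = pd.read_csv(stream, index_col=0, float_precision="round_trip")
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return cls(frame)

    def to_csv(self, stream) -> None:
        self.frame.to_csv(stream)


@dataclass(frozen=True)
class CutoffSchedule:
    """Strictly ascending similarity cutoffs in (0, 1]."""

    cutoffs: tuple[float, ...]

    def __post_init__(self) -> None:
        cs = tuple(float(c) for c in self.cutoffs)
        if not cs:
            raise ValueError("cutoff schedule is empty")
        if any(not (0 < c <= 1) for c in cs):
            raise ValueError("cutoffs must lie in (0, 1]")
        if any(b <= a for a, b in zip(cs, cs[1:])):
            raise ValueError("cutoffs must be strictly ascending")
        object.__setattr__(self, "cutoffs", cs)

    def __iter__(self):
        return iter(self.cutoffs)

    def __len__(self) -> int:
        return len(self.cutoffs)


#: 13-point default schedule for structural-similarity-style matrices
STRUCTURAL_SCHEDULE = CutoffSchedule(tuple(np.round(np.arange(0.35, 0.951, 0.05), 2)))
#: 11-point default schedule for sequence-similarity-style matrices
SEQUENCE_SCHEDULE = CutoffSchedule(tuple(np.round(np.linspace(0.20, 0.95, 11), 2)))


@dataclass(frozen=True)
class NestedPartition:
    """Retained training-id sets per cutoff, nested by construction."""

    retained: dict[float, frozenset]
    full_train_ids: frozenset

    def sizes(self) -> list[tuple[float, int]]:
        return [(c, len(ids)) for c, ids in sorted(self.retained.items())]

    @property
    def cutoffs(self) -> list[float]:
        return sorted(self.retained)


def max_test_similarity(matrix: SimilarityMatrix, train_id) -> float:
    """Highest similarity of one training complex to any test complex."""
    if train_id not in matrix.frame.index:
        raise KeyError(f"unknown training id {train_id!r}")
    return float(matrix.frame.loc[train_id].max())


def build_nested_sets(matrix: SimilarityMatrix, cutoffs: CutoffSchedule) -> NestedPartition:
    """Retain, per cutoff c, the training complexes with max similarity <= c.

    The closed boundary means a training complex tied exactly at the
    cutoff stays in; removal requires a strictly above-cutoff similarity
    to at least one test complex.
    """
    row_max = matrix.row_max()
    retained = {
        float(c): frozenset(row_max.index[row_max.to_numpy() <= c])
        for c in cutoffs
    }
    return NestedPartition(retained=retained, full_train_ids=frozenset(matrix.train_ids))


def percent_of_total(n_retained: int, total_n: int) -> float:
    """Share of the full training set, in percent, to one decimal."""
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    if n_retained > total_n:
        raise ValueError("retained count exceeds total")
    return round(100.0 * n_retained / total_n, 1)


def partition_report(partition: NestedPartition, total_n: int) -> pd.DataFrame:
    """Tabulate (cutoff, n_train, percent of the full training set)."""
    if total_n < max((len(s) for s in partition.retained.values()), default=0):
        raise ValueError("total_n smaller than a retained set")
    rows = [
        {"cutoff": c, "n_train": n, "percent": percent_of_total(n, total_n)}
        for c, n in partition.sizes()
    ]
    return pd.DataFrame(rows, columns=["cutoff", "n_train", "percent"])
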