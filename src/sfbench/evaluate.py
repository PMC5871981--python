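"""Scoring-power evaluation and learning-curve assembly.

Scoring power is measured as the Pearson product-moment correlation (Rp)
between predicted and measured binding affinities of a fixed, diverse test
set.  For stochastic regressors the protocol trains several instances per
configuration; this module summarises the per-repeat Rp values (mean,
median, min, max, range) and assembles the learning-curve table across
(scoring function x cutoff) cells, training on each cutoff's retained
complexes only and always predicting the same test set.

The ``gap_ratio`` statistic relates the median advantage of a stochastic
scoring function over a deterministic one to the stochastic variability
range, the argument used in place of significance testing: when the gap is
tens of times the repeat-to-repeat range, p-values add nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable
from .partition import NestedPartition
from .regress import ModelSpec, repeat_fit_predict

__all__ = [
    "UndefinedCorrelationError",
    "RepeatSummary",
    "LearningCurveTable",
    "CurveInputs",
    "pearson_rp",
    "summarize_repeats",
    "gap_ratio",
    "build_learning_curve",
    "plot_learning_curve",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


def pearson_rp(y_true, y_pred) -> float:
    """Sample Pearson correlation between measured and predicted affinities.

    Raises ``UndefinedCorrelationError`` (never silently returns 0) when
    either vector is constant.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    if y_true.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise UndefinedCorrelationError("constant input; correlation undefined")
    return float(np.corrcoef(y_true, y_pred)[0, 1])


@dataclass(frozen=True)
class RepeatSummary:
    """Per (scoring function, cutoff) cell of the learning curve."""

    sf_name: str
    cutoff: float
    n_train: int
    rp_values: tuple[float, ...]
    trainable: bool = True

    @property
    def mean_rp(self) -> float:
        return float(np.mean(self.rp_values)) if self.trainable else float("nan")

    @property
    def median_rp(self) -> float:
        return float(median(self.rp_values)) if self.trainable else float("nan")

    @property
    def min_rp(self) -> float:
        return float(min(self.rp_values)) if self.trainable else float("nan")

    @property
    def max_rp(self) -> float:
        return float(max(self.rp_values)) if self.trainable else float("nan")

    @property
    def range_rp(self) -> float:
        return self.max_rp - self.min_rp if self.trainable else float("nan")


def summarize_repeats(sf_name: str, cutoff: float, n_train: int,
                      predictions: Sequence[np.ndarray], y_true) -> RepeatSummary:
    """Compute per-repeat Rp values and their summary statistics."""
    if not len(predictions):
        raise ValueError("empty prediction list")
    rp = tuple(pearson_rp(y_true, p) for p in predictions)
    return RepeatSummary(sf_name, float(cutoff), int(n_train), rp)


def gap_ratio(median_rp_a: float, rp_b: float, range_a: float) -> float:
    """(median Rp of the stochastic SF - Rp of the comparator) / repeat range.

    A large value says the performance gap dwarfs the stochastic
    variability; ``range_a`` must be positive (a deterministic comparator
    has no stochastic scale).
    """
    if range_a <= 0:
        raise ValueError("range_a must be positive")
    return (median_rp_a - rp_b) / range_a


@dataclass(frozen=True)
class CurveInputs:
    """Descriptor tables (per scheme) and affinities for train and test."""

    train_tables: dict  # scheme -> DescriptorTable over all training ids
    test_tables: dict   # scheme -> DescriptorTable over the fixed test set
    y_train: pd.Series  # pKd, indexed by training id
    y_test: pd.Series   # pKd, indexed by test id


class LearningCurveTable:
    """Rows of RepeatSummary over (scoring function x cutoff)."""

    def __init__(self, rows: list[RepeatSummary]):
        seen = set()
        for r in rows:
            key = (r.sf_name, r.cutoff)
            if key in seen:
                raise ValueError(f"duplicate learning-curve cell {key}")
            seen.add(key)
        self.rows = rows

    def row(self, sf_name: str, cutoff: float) -> RepeatSummary:
        for r in self.rows:
            if r.sf_name == sf_name and r.cutoff == cutoff:
                return r
        raise KeyError((sf_name, cutoff))

    def sf_rows(self, sf_name: str) -> list[RepeatSummary]:
        return sorted((r for r in self.rows if r.sf_name == sf_name), key=lambda r: r.cutoff)

    @property
    def sf_names(self) -> list[str]:
        out = []
        for r in self.rows:
            if r.sf_name not in out:
                out.append(r.sf_name)
        return out

    def to_long_frame(self) -> pd.DataFrame:
        """Long form: one row per (sf, cutoff, repeat)."""
        records = [
            {"sf": r.sf_name, "cutoff": r.cutoff, "n_train": r.n_train,
             "repeat": k, "rp": round(rp, 3)}
            for r in self.rows if r.trainable
            for k, rp in enumerate(r.rp_values)
        ]
        return pd.DataFrame(records, columns=["sf", "cutoff", "n_train", "repeat", "rp"])

    def to_summary_frame(self) -> pd.DataFrame:
        """Summary form: one row per (sf, cutoff), Rp to 3 decimals."""
        records = []
        for r in self.rows:
            rec = {"sf": r.sf_name, "cutoff": r.cutoff, "n_train": r.n_train}
            if r.trainable:
                rec.update(
                    mean_rp=round(r.mean_rp, 3), median_rp=round(r.median_rp, 3),
                    min_rp=round(r.min_rp, 3), max_rp=round(r.max_rp, 3),
                    range_rp=round(r.range_rp, 3),
                )
            else:
                rec.update(mean_rp=None, median_rp=None, min_rp=None,
                           max_rp=None, range_rp=None)
            records.append(rec)
        return pd.DataFrame(
            records,
            columns=["sf", "cutoff", "n_train", "mean_rp", "median_rp",
                     "min_rp", "max_rp", "range_rp"],
        )


def build_learning_curve(
    data: CurveInputs,
    partition: NestedPartition,
    sf_configs: Sequence[tuple[str, str, ModelSpec]],
) -> LearningCurveTable:
    """Train every scoring function on every nested set; test once per cell.

    ``sf_configs`` is a roster of (name, descriptor scheme, ModelSpec).
    The test set is identical across all cells.  Cutoffs retaining fewer
    than 2 training complexes are kept in the table but flagged
    untrainable (null Rp) rather than silently dropped.
    """
    rows: list[RepeatSummary] = []
    for sf_name, scheme, spec in sf_configs:
        if scheme not in data.train_tables or scheme not in data.test_tables:
            raise ValueError(f"no descriptor tables for scheme {scheme!r}")
        train_table = data.train_tables[scheme]
        test_table = data.test_tables[scheme]
        y_test = data.y_test.loc[test_table.ids]
        for cutoff in partition.cutoffs:
            # stable order: keep the full-table ordering, not set order
            ids = [i for i in train_table.ids if i in partition.retained[cutoff]]
            if len(ids) < 2:
                rows.append(RepeatSummary(sf_name, cutoff, len(ids), (), trainable=False))
                continue
            X_train = train_table.subset(ids)
            y_train = data.y_train.loc[ids]
            preds = repeat_fit_predict(X_train, y_train.to_numpy(), test_table, spec)
            rows.append(summarize_repeats(sf_name, cutoff, len(ids), preds,
                                          y_test.to_numpy()))
    return LearningCurveTable(rows)


def plot_learning_curve(table: LearningCurveTable, path, statistic: str = "mean_rp") -> None:
    """Plot Rp against the number of training samples, one line per SF.

    The horizontal axis is n_train (not the cutoff), so the plot reads as
    a learning curve.  Requires matplotlib.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = table.to_summary_frame().dropna(subset=[statistic])
    fig, ax = plt.subplots(figsize=(7, 5))
    for sf in table.sf_names:
        sub = frame[frame["sf"] == sf].sort_values("n_train")
        if len(sub):
            ax.plot(sub["n_train"], sub[statistic], marker="o", label=sf)
    ax.set_xlabel("number of training samples")
    ax.set_ylabel(f"test-set Rp ({statistic.replace('_rp', '')} of repeats)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
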