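"""Regression engines for the scoring-function comparison.

Two families are supported, chosen to mirror how classical and
machine-learning scoring functions are actually built:

- ``MLR``: ordinary least squares with intercept.  Deterministic --
  refitting on identical input yields bit-identical coefficients -- and
  minimum-norm when the design is rank-deficient.  This is the regression
  behind classical empirical scoring functions.

- ``RF``: a random forest of regression trees, each grown on a bootstrap
  resample of size n with ceil(p/3) candidate features per split and
  unlimited depth (the common RF-regression defaults).  Stochastic, but a
  pure function of the seed.

The repeat protocol trains ``n_repeats`` instances per configuration
(repeat r uses seed ``base_seed + r``) and returns all prediction vectors;
for MLR the model is fitted once and replicated, since every repeat would
be identical anyway.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .descriptors import DescriptorTable

__all__ = ["ModelSpec", "FittedModel", "fit_mlr", "fit_rf", "repeat_fit_predict",
           "save_model", "load_model"]


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one scoring-function regression.

    ``features_per_split`` accepts the rule name ``"third"`` (ceil(p/3),
    the RF-regression default) or an explicit integer.
    """

    kind: str  # "MLR" | "RF"
    n_trees: int = 500
    features_per_split: object = "third"
    n_repeats: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("MLR", "RF"):
            raise ValueError(f"kind must be 'MLR' or 'RF', got {self.kind!r}")
        if self.n_trees < 1 or self.n_repeats < 1:
            raise ValueError("n_trees and n_repeats must be >= 1")

    def max_features(self, p: int) -> int:
        if self.features_per_split == "third":
            return max(1, math.ceil(p / 3))
        return int(self.features_per_split)


@dataclass
class FittedModel:
    """A trained predictor plus the metadata needed to audit it."""

    kind: str
    predictor: object
    seed: int | None
    training_ids: tuple
    scheme: str

    def predict(self, X: DescriptorTable | np.ndarray) -> np.ndarray:
        if isinstance(X, DescriptorTable):
            if X.scheme != self.scheme:
                raise ValueError(f"scheme mismatch: model {self.scheme}, data {X.scheme}")
            X = X.features().to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if self.kind == "MLR":
            intercept, coefs = self.predictor
            return intercept + X @ coefs
        return self.predictor.predict(X)


def _design(X: DescriptorTable | np.ndarray):
    if isinstance(X, DescriptorTable):
        return X.features().to_numpy(dtype=float), tuple(X.ids), X.scheme
    return np.asarray(X, dtype=float), (), "external"


def fit_mlr(X: DescriptorTable | np.ndarray, y) -> FittedModel:
    """Ordinary least squares with intercept (minimum-norm on rank deficiency).

    Solved through numpy's SVD-based least squares, so identical inputs give
    bit-identical coefficients.
    """
    A, ids, scheme = _design(X)
    y = np.asarray(y, dtype=float)
    n, p = A.shape
    if n != len(y):
        raise ValueError("X and y lengths differ")
    if n < 2:
        raise ValueError("need at least 2 training samples")
    design = np.hstack([np.ones((n, 1)), A])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p + 1:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {p + 1}); minimum-norm solution",
            stacklevel=2,
        )
    return FittedModel("MLR", (coef[0], coef[1:]), None, ids, scheme)


def fit_rf(X: DescriptorTable | np.ndarray, y, spec: ModelSpec, seed: int) -> FittedModel:
    """Random forest regression per ``spec``; a pure function of the seed."""
    if spec.kind != "RF":
        raise ValueError("fit_rf requires an RF ModelSpec")
    A, ids, scheme = _design(X)
    y = np.asarray(y, dtype=float)
    if A.shape[0] != len(y):
        raise ValueError("X and y lengths differ")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    forest = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=spec.max_features(A.shape[1]),
        bootstrap=True,
        n_jobs=1,
        random_state=int(seed) % (2**31),
    )
    forest.fit(A, y)
    return FittedModel("RF", forest, seed, ids, scheme)


def repeat_fit_predict(
    X_train: DescriptorTable | np.ndarray,
    y_train,
    X_test: DescriptorTable | np.ndarray,
    spec: ModelSpec,
) -> list[np.ndarray]:
    """Train ``spec.n_repeats`` instances and predict the fixed test set.

    MLR is deterministic: it is fitted once and the prediction vector is
    replicated.  RF repeats differ only through seed = base_seed + r.
    """
    if isinstance(X_train, DescriptorTable) and isinstance(X_test, DescriptorTable):
        if X_train.scheme != X_test.scheme:
            raise ValueError("train/test descriptor schemes differ")
    if spec.kind == "MLR":
        pred = fit_mlr(X_train, y_train).predict(X_test)
        return [pred.copy() for _ in range(spec.n_repeats)]
    return [
        fit_rf(X_train, y_train, spec, spec.base_seed + r).predict(X_test)
        for r in range(spec.n_repeats)
    ]


_PERSIST_VERSION = 1


def save_model(model: FittedModel, path) -> None:
    """Serialize a fitted model with its audit metadata."""
    joblib.dump(
        {
            "format_version": _PERSIST_VERSION,
            "kind": model.kind,
            "predictor": model.predictor,
            "seed": model.seed,
            "training_ids": model.training_ids,
            "scheme": model.scheme,
        },
        path,
    )


def load_model(path) -> FittedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != _PERSIST_VERSION:
        raise ValueError(f"unsupported model container version {payload.get('format_version')!r}")
    return FittedModel(
        kind=payload["kind"],
        predictor=payload["predictor"],
        seed=payload["seed"],
        training_ids=tuple(payload["training_ids"]),
        scheme=payload["scheme"],
    )
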