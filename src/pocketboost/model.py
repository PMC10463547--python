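"""Gradient-boosted regression trees with grid-searched hyperparameters.

The learner is XGBoost's regression booster.  Three hyperparameters are
searched on a fixed grid — number of boosting rounds, maximum tree depth and
learning rate — with every other booster setting left at its library
default; those defaults are pinned into the model artifact for
reproducibility.  Selection uses internal k-fold cross-validation on the
training partition only: for each grid point the mean held-out Pearson R is
computed over the k folds, and the point with the highest mean R wins (ties
broken by lower mean RMSE, then by smaller round count, shallower depth and
smaller learning rate, giving a total order).

Everything is deterministic for a fixed seed: fold assignment, grid
iteration order and the booster itself (single-threaded by default).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold
from xgboost import Booster, XGBRegressor

from .dataset import Dataset
from .errors import DataError, SchemaError
from .errors import UndefinedCorrelationError
from .evaluate import pearson_r, rmse
from .featurize import schema_hash


@dataclass(frozen=True)
class HyperGrid:
    """The searched hyperparameter grid; all other settings stay at defaults."""

    n_rounds: tuple[int, ...] = (500, 1000, 1500, 2000)
    max_depth: tuple[int, ...] = (2, 4, 6, 8)
    learning_rate: tuple[float, ...] = (0.001, 0.01, 0.1, 0.2, 0.3)

    def points(self) -> list[tuple[int, int, float]]:
        """All combinations in deterministic (rounds, depth, rate) order."""
        return list(itertools.product(self.n_rounds, self.max_depth, self.learning_rate))

    def __len__(self) -> int:
        return len(self.points())

    @classmethod
    def default(cls) -> "HyperGrid":
        return cls()

    @classmethod
    def reduced(cls) -> "HyperGrid":
        """A 2x2x2 grid for desk-scale experiments on synthetic data."""
        return cls(n_rounds=(300, 600), max_depth=(2, 4), learning_rate=(0.1, 0.2))


@dataclass(frozen=True)
class ModelSpec:
    """A chosen grid point plus the CV score that selected it."""

    n_rounds: int
    max_depth: int
    learning_rate: float
    selection_metric: float = float("nan")  # mean internal-CV Pearson R
    selection_rmse: float = float("nan")
    seed: int = 0


# Booster settings outside the grid, pinned for reproducibility.
PINNED_BOOSTER_DEFAULTS = {
    "tree_method": "hist",
    "n_jobs": 1,
    "verbosity": 0,
    "objective": "reg:squarederror",
}


def _make_booster(spec: ModelSpec, seed: int, n_jobs: int = 1) -> XGBRegressor:
    params = dict(PINNED_BOOSTER_DEFAULTS)
    params["n_jobs"] = n_jobs
    return XGBRegressor(
        n_estimators=spec.n_rounds,
        max_depth=spec.max_depth,
        learning_rate=spec.learning_rate,
        random_state=seed,
        **params,
    )


def evaluate_grid(
    train: Dataset, grid: HyperGrid, k: int = 5, seed: int = 0, n_jobs: int = 1
) -> list[tuple[tuple[int, int, float], float, float]]:
    """Internal-CV scores for every grid point: (point, mean R, mean RMSE).

    The fold assignment is shared across grid points so scores are paired.
    """
    n = len(train)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if n // k < 2:
        raise ValueError("each internal fold needs at least 2 held-out rows for Pearson R")
    if not len(grid):
        raise ValueError("hyperparameter grid is empty")
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(train.X))
    scores = []
    for point in grid.points():
        spec = ModelSpec(*point, seed=seed)
        rs, es = [], []
        for tr, va in folds:
            booster = _make_booster(spec, seed, n_jobs)
            booster.fit(train.X[tr], train.y[tr])
            pred = booster.predict(train.X[va])
            try:
                rs.append(pearson_r(train.y[va], pred))
            except UndefinedCorrelationError:
                # constant predictions (e.g. a vanishing learning rate):
                # worthless by fiat, never a winner
                rs.append(float("-inf"))
            es.append(rmse(train.y[va], pred))
        scores.append((point, float(np.mean(rs)), float(np.mean(es))))
    return scores


def grid_search(
    train: Dataset, grid: HyperGrid | None = None, k: int = 5, seed: int = 0,
    n_jobs: int = 1,
) -> ModelSpec:
    """Pick the grid point with the best mean internal-CV Pearson R.

    Ties go to the lower mean RMSE, then to the smaller round count,
    shallower depth and smaller learning rate.
    """
    grid = grid or HyperGrid.default()
    scores = evaluate_grid(train, grid, k=k, seed=seed, n_jobs=n_jobs)
    best_point, best_r, best_rmse = max(
        scores, key=lambda s: (s[1], -s[2], -s[0][0], -s[0][1], -s[0][2])
    )
    return ModelSpec(
        n_rounds=best_point[0], max_depth=best_point[1], learning_rate=best_point[2],
        selection_metric=best_r, selection_rmse=best_rmse, seed=seed,
    )


@dataclass
class TrainedModel:
    """A fitted booster bound to the feature schema it was trained on."""

    booster: XGBRegressor
    feature_schema: tuple[str, ...]
    spec: ModelSpec

    @property
    def schema_hash(self) -> str:
        return schema_hash(self.feature_schema)

    def predict(self, X: np.ndarray, feature_names: tuple[str, ...] | None = None) -> np.ndarray:
        if feature_names is not None and schema_hash(feature_names) != self.schema_hash:
            raise SchemaError("feature schema does not match the trained model")
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            return np.zeros(0)
        if X.ndim != 2 or X.shape[1] != len(self.feature_schema):
            raise SchemaError(
                f"expected {len(self.feature_schema)} feature columns, got {X.shape}"
            )
        pred = self.booster.predict(X)
        if not np.isfinite(pred).all():
            raise DataError("model produced non-finite predictions")
        return np.asarray(pred, dtype=float)


def train(dataset: Dataset, spec: ModelSpec, seed: int = 0, n_jobs: int = 1) -> TrainedModel:
    """Fit the booster at one grid point on the full training partition."""
    bad = ~np.isfinite(dataset.X).all(axis=1) | ~np.isfinite(dataset.y)
    if bad.any():
        first = int(np.flatnonzero(bad)[0])
        raise DataError(f"non-finite feature or target value in row {dataset.ids[first]!r}")
    booster = _make_booster(spec, seed, n_jobs)
    booster.fit(dataset.X, dataset.y)
    return TrainedModel(booster=booster, feature_schema=dataset.feature_names, spec=spec)


def predict(model: TrainedModel, X: np.ndarray | Dataset) -> np.ndarray:
    """One finite prediction per row; refuses mismatched schemas."""
    if isinstance(X, Dataset):
        return model.predict(X.X, X.feature_names)
    return model.predict(X)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize booster + schema + spec (JSON sidecar next to the booster)."""
    path = Path(path)
    # persist the raw booster; the sklearn wrapper is rebuilt from the sidecar
    model.booster.get_booster().save_model(str(path))
    sidecar = {
        "feature_schema": list(model.feature_schema),
        "schema_hash": model.schema_hash,
        "spec": {
            "n_rounds": model.spec.n_rounds,
            "max_depth": model.spec.max_depth,
            "learning_rate": model.spec.learning_rate,
            "selection_metric": model.spec.selection_metric,
            "selection_rmse": model.spec.selection_rmse,
            "seed": model.spec.seed,
        },
        "pinned_defaults": PINNED_BOOSTER_DEFAULTS,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec = ModelSpec(**sidecar["spec"])
    raw = Booster()
    raw.load_model(str(path))
    booster = _make_booster(spec, spec.seed)
    booster._Booster = raw  # marks the wrapper as fitted
    return TrainedModel(
        booster=booster, feature_schema=tuple(sidecar["feature_schema"]), spec=spec
    )
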