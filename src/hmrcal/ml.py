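"""Gradient-boosted regression of conversion coefficients on collimator design.

Given a table of (hole diameter, septal thickness, length) -> compensated
conversion coefficient rows generated by the simulator, this module
reproduces the published training protocol: a 3:2 train/validation split,
an exhaustive grid search over squared-error gradient-boosted trees with
fourfold cross-validation, RMSE evaluation, permutation feature
importance, and an ordinary-least-squares baseline on the same features.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold, train_test_split

from .collimator import CollimatorSpec

logger = logging.getLogger("hmrcal")

__all__ = [
    "FEATURES",
    "TARGET",
    "DEFAULT_GRID",
    "TrainedEstimator",
    "feature_subsets",
    "split_dataset",
    "train_gbm",
    "train_linear",
    "rmse",
    "permutation_importances",
    "predict_coefficient",
    "save_model",
    "load_model",
]

FEATURES = ("d_mm", "t_mm", "L_mm")
TARGET = "compensated_cc"

MIN_FIT_ROWS = 20

# Discretization of the published hyperparameter ranges (learning rate
# 0.01-0.5, estimators 1-100, depth 1-8); includes the published tuned
# point (0.33, 25, 2).
DEFAULT_GRID = {
    "learning_rate": [0.01, 0.05, 0.1, 0.2, 0.33, 0.5],
    "n_estimators": [5, 10, 25, 50, 100],
    "max_depth": [1, 2, 3, 4, 5, 6, 7, 8],
}


@dataclass
class TrainedEstimator:
    """A fitted regressor plus its training provenance."""

    model_kind: str  # "gbm" | "linear"
    estimator: object
    feature_subset: tuple[str, ...]
    hyperparameters: dict = field(default_factory=dict)
    cv_results: pd.DataFrame | None = None
    validation_rmse: float | None = None
    importances: pd.DataFrame | None = None

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(table.loc[:, list(self.feature_subset)].to_numpy())


def feature_subsets() -> list[tuple[str, ...]]:
    """All seven nonempty subsets of the three collimator features."""
    subsets = []
    for k in (1, 2, 3):
        subsets.extend(itertools.combinations(FEATURES, k))
    return subsets


def _check_table(table: pd.DataFrame, min_rows: int = MIN_FIT_ROWS) -> None:
    cols = [*FEATURES, TARGET]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    if table.loc[:, cols].isna().any().any():
        raise ValueError("feature table contains missing values")
    if (table.loc[:, list(FEATURES)] <= 0).any().any():
        raise ValueError("collimator features must be positive")
    if len(table) < min_rows:
        raise ValueError(f"need >= {min_rows} rows, got {len(table)}")


def split_dataset(
    table: pd.DataFrame, seed: int = 0, ratio: tuple[int, int] = (3, 2)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random, seeded train/validation split in the given ratio (3:2)."""
    if len(table) < 5:
        raise ValueError("need at least 5 rows to split 3:2")
    frac_val = ratio[1] / (ratio[0] + ratio[1])
    train, val = train_test_split(table, test_size=frac_val, random_state=seed)
    return train, val


def train_gbm(
    train: pd.DataFrame,
    feature_subset: tuple[str, ...] = FEATURES,
    grid: dict | None = None,
    folds: int = 4,
    seed: int = 0,
) -> TrainedEstimator:
    """Grid-search a squared-error gradient-boosted regressor with k-fold CV.

    Selects the hyperparameters with the best mean cross-validated RMSE
    and refits on the full training set.  Remaining hyperparameters stay
    at library defaults.
    """
    _check_table(train)
    grid = dict(grid or DEFAULT_GRID)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid must be nonempty")
    if any(d < 1 for d in grid.get("max_depth", [1])):
        raise ValueError("max_depth grid values must be >= 1")
    if folds < 2:
        raise ValueError("need at least 2 CV folds")

    X = train.loc[:, list(feature_subset)].to_numpy()
    y = train[TARGET].to_numpy()
    search = GridSearchCV(
        GradientBoostingRegressor(loss="squared_error", random_state=seed),
        param_grid=grid,
        scoring="neg_root_mean_squared_error",
        cv=KFold(n_splits=folds, shuffle=True, random_state=seed),
        refit=True,
        n_jobs=None,
    )
    search.fit(X, y)
    logger.info("GBM grid search best params: %s", search.best_params_)
    return TrainedEstimator(
        model_kind="gbm",
        estimator=search.best_estimator_,
        feature_subset=tuple(feature_subset),
        hyperparameters=dict(search.best_params_),
        cv_results=pd.DataFrame(search.cv_results_),
    )


def train_linear(
    train: pd.DataFrame, feature_subset: tuple[str, ...] = FEATURES
) -> TrainedEstimator:
    """Ordinary least squares on the collimator parameters."""
    _check_table(train, min_rows=len(feature_subset) + 2)
    X = train.loc[:, list(feature_subset)].to_numpy()
    y = train[TARGET].to_numpy()
    if np.linalg.matrix_rank(np.column_stack([X, np.ones(len(X))])) < X.shape[1] + 1:
        raise ValueError("rank-deficient design matrix")
    est = LinearRegression().fit(X, y)
    return TrainedEstimator(
        model_kind="linear",
        estimator=est,
        feature_subset=tuple(feature_subset),
        hyperparameters={},
    )


def rmse(model: TrainedEstimator, validation: pd.DataFrame) -> float:
    """Root-mean-square prediction error on the validation rows."""
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    pred = model.predict(validation)
    err = validation[TARGET].to_numpy() - pred
    value = float(np.sqrt(np.mean(err**2)))
    model.validation_rmse = value
    return value


def permutation_importances(
    model: TrainedEstimator,
    table: pd.DataFrame,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean +/- SD increase in validation MSE when one feature is shuffled."""
    if repeats < 5:
        raise ValueError("need at least 5 permutation repeats")
    X = table.loc[:, list(model.feature_subset)].to_numpy()
    y = table[TARGET].to_numpy()
    res = _sk_permutation_importance(
        model.estimator,
        X,
        y,
        scoring="neg_mean_squared_error",
        n_repeats=repeats,
        random_state=seed,
    )
    out = pd.DataFrame(
        {
            "feature": list(model.feature_subset),
            "importance_mean": res.importances_mean,
            "importance_sd": res.importances_std,
        }
    )
    model.importances = out
    return out


def predict_coefficient(model: TrainedEstimator, c: CollimatorSpec) -> float:
    """Predict the compensated conversion coefficient for one design."""
    if model.estimator is None:
        raise RuntimeError("model is not fitted")
    features = dict(zip(FEATURES, c.as_features()))
    row = pd.DataFrame([[features[f] for f in model.feature_subset]],
                       columns=list(model.feature_subset))
    return float(model.estimator.predict(row.to_numpy())[0])


def save_model(model: TrainedEstimator, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> TrainedEstimator:
    return joblib.load(path)
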