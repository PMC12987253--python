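"""Weighted heterogeneous tree ensemble for biomass regression.

Three base learners — random forest (RF), extra trees (ET), and
histogram gradient boosting (HGB) — are fitted on robust-scaled
features (median centering, IQR scaling) and combined by weighted soft
voting:

    yhat = w_RF yhat_RF + w_ET yhat_ET + w_HGB yhat_HGB,   w on the simplex.

The weights are determined on the training data only: 10-fold
out-of-fold predictions of each base learner are combined over a
simplex grid (step 0.05, plus the exact equal-weight point) and the
combination maximizing out-of-fold R^2 is kept, with ties broken toward
equal weights.  Because the grid contains the simplex vertices, the
ensemble's out-of-fold R^2 can never fall below the best single base
learner's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.preprocessing import RobustScaler

from .feature_table import TARGET_COLUMN, FeatureTable

BASE_LEARNERS = ("RF", "ET", "HGB")

#: Published tuned hyperparameters used as library defaults.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "RF": {
        "n_estimators": 1000,
        "max_depth": 15,
        "min_samples_split": 5,
        "min_samples_leaf": 2,
        "max_features": "sqrt",
    },
    "ET": {
        "n_estimators": 1200,
        "max_depth": None,
        "min_samples_split": 4,
        "min_samples_leaf": 1,
        "max_features": "sqrt",
        "bootstrap": False,
    },
    "HGB": {
        "max_iter": 1000,
        "learning_rate": 0.05,
        "max_depth": 8,
        "min_samples_leaf": 5,
        "l2_regularization": 1.0,
    },
}

WEIGHT_GRID_STEP = 0.05
EQUAL_WEIGHTS = np.array([1.0, 1.0, 1.0]) / 3.0


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification (floor rule on the train side)."""

    train_fraction: float = 0.85
    seed: int = 0
    n_folds: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0, 1); got {self.train_fraction}")


@dataclass
class RobustScaleParams:
    """Median/IQR scaling parameters (unit scale where IQR = 0)."""

    center: np.ndarray
    scale: np.ndarray
    columns: list[str]

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return (X[self.columns].to_numpy() - self.center) / self.scale


def _make_learner(name: str, params: Mapping, seed: int):
    if name == "RF":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if name == "ET":
        return ExtraTreesRegressor(random_state=seed, n_jobs=1, **params)
    if name == "HGB":
        return HistGradientBoostingRegressor(random_state=seed, **params)
    raise ValueError(f"unknown base learner {name!r}")


def _derive_seed(root: int, salt: int) -> int:
    return int(np.random.SeedSequence([root, salt]).generate_state(1)[0] % (2**31 - 1))


def split_train_test(
    table: FeatureTable, spec: SplitSpec
) -> tuple[FeatureTable, FeatureTable]:
    """Seeded uniform random split without stratification.

    Train size is floor(train_fraction * n) — at n = 270 and fraction
    0.85 this yields the canonical 229/41 partition.
    """
    n = len(table.data)
    if n < 20:
        raise ValueError(f"split needs >= 20 rows; got {n}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_train = int(np.floor(spec.train_fraction * n))
    train_idx, test_idx = np.sort(order[:n_train]), np.sort(order[n_train:])
    make = lambda idx: FeatureTable(
        data=table.data.iloc[idx].reset_index(drop=True), provenance=dict(table.provenance)
    )
    return make(train_idx), make(test_idx)


def simplex_weight_grid(step: float = WEIGHT_GRID_STEP) -> np.ndarray:
    """All weight triples on the simplex lattice of the given step,
    plus the exact equal-weights point (used as the tie-break target)."""
    n = int(round(1.0 / step))
    grid = [
        (i / n, j / n, (n - i - j) / n)
        for i, j in product(range(n + 1), repeat=2)
        if i + j <= n
    ]
    grid.append(tuple(EQUAL_WEIGHTS))
    return np.array(grid)


@dataclass
class EnsembleModel:
    """Fitted RF+ET+HGB soft-voting ensemble with its scaler and weights."""

    learners: dict[str, object]
    weights: np.ndarray  # (3,) aligned with BASE_LEARNERS
    scaler: RobustScaleParams
    feature_columns: list[str]
    hyperparameters: dict[str, dict]
    seed: int
    oof_r2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (3,) or np.any(self.weights < -1e-12):
            raise ValueError("weights must be three non-negative values")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1; got {self.weights.sum()}")

    def base_predictions(self, rows: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_columns if c not in rows.columns]
        if missing:
            raise KeyError(f"prediction rows missing feature columns: {missing}")
        Xs = self.scaler.transform(rows)
        return pd.DataFrame(
            {name: self.learners[name].predict(Xs) for name in BASE_LEARNERS}, index=rows.index
        )

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Weighted soft-voting prediction (kg m^-2) per row."""
        base = self.base_predictions(rows)
        return base.to_numpy() @ self.weights

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "weights": dict(zip(BASE_LEARNERS, self.weights.tolist())),
            "scaler": {
                "center": self.scaler.center.tolist(),
                "scale": self.scaler.scale.tolist(),
                "columns": self.scaler.columns,
            },
            "feature_columns": self.feature_columns,
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
            "oof_r2": self.oof_r2,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for name in BASE_LEARNERS:
            joblib.dump(self.learners[name], outdir / f"{name}.joblib")
        return outdir

    @classmethod
    def load(cls, outdir: str | Path) -> "EnsembleModel":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        scaler = RobustScaleParams(
            center=np.array(manifest["scaler"]["center"]),
            scale=np.array(manifest["scaler"]["scale"]),
            columns=manifest["scaler"]["columns"],
        )
        learners = {name: joblib.load(outdir / f"{name}.joblib") for name in BASE_LEARNERS}
        return cls(
            learners=learners,
            weights=np.array([manifest["weights"][n] for n in BASE_LEARNERS]),
            scaler=scaler,
            feature_columns=manifest["feature_columns"],
            hyperparameters=manifest["hyperparameters"],
            seed=manifest["seed"],
            oof_r2=manifest.get("oof_r2", {}),
        )


def _fit_scaler(X: pd.DataFrame) -> RobustScaleParams:
    scaler = RobustScaler(quantile_range=(25.0, 75.0))
    scaler.fit(X.to_numpy())
    # sklearn substitutes unit scale where the IQR collapses to zero
    return RobustScaleParams(
        center=scaler.center_.copy(), scale=scaler.scale_.copy(), columns=list(X.columns)
    )


def out_of_fold_predictions(
    X: np.ndarray,
    y: np.ndarray,
    hyperparameters: Mapping[str, Mapping],
    seed: int,
    n_folds: int = 10,
) -> pd.DataFrame:
    """Deterministic K-fold out-of-fold predictions for all three learners."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=_derive_seed(seed, 1))
    oof = {name: np.empty(len(y)) for name in BASE_LEARNERS}
    for fold, (tr, va) in enumerate(kf.split(X)):
        for name in BASE_LEARNERS:
            learner = _make_learner(name, hyperparameters[name], _derive_seed(seed, 100 + fold))
            learner.fit(X[tr], y[tr])
            oof[name][va] = learner.predict(X[va])
    return pd.DataFrame(oof)


def search_weights(oof: pd.DataFrame, y: np.ndarray, step: float = WEIGHT_GRID_STEP) -> np.ndarray:
    """Simplex-grid weight search maximizing out-of-fold R^2.

    Ties (within 1e-12 of the best score) break toward the weight triple
    closest to equal weights, then lexicographically — so three
    identical base learners yield exactly (1/3, 1/3, 1/3).
    """
    grid = simplex_weight_grid(step)
    P = oof[list(BASE_LEARNERS)].to_numpy()
    scores = np.array([r2_score(y, P @ w) for w in grid])
    best = scores.max()
    tied = grid[scores >= best - 1e-12]
    dist = np.linalg.norm(tied - EQUAL_WEIGHTS, axis=1)
    candidates = tied[dist <= dist.min() + 1e-12]
    order = np.lexsort(candidates.T[::-1])  # deterministic among equidistant ties
    return candidates[order[0]]


def fit_ensemble(
    train: FeatureTable,
    feature_columns: Sequence[str] | None = None,
    hyperparameters: Mapping[str, Mapping] | None = None,
    seed: int = 0,
    n_folds: int = 10,
) -> EnsembleModel:
    """Fit scaler, base learners, and soft-voting weights on training data.

    The scaler and the out-of-fold weight search see only ``train``; the
    test set plays no role until final evaluation.
    """
    hp = {k: dict(v) for k, v in DEFAULT_HYPERPARAMETERS.items()}
    if hyperparameters:
        for k, v in hyperparameters.items():
            hp[k].update(v)
    cols = list(feature_columns) if feature_columns is not None else train.feature_columns
    missing = [c for c in cols if c not in train.data.columns]
    if missing:
        raise KeyError(f"training table missing feature columns: {missing}")

    X_raw = train.data[cols]
    y = train.data[TARGET_COLUMN].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("training target contains missing values")
    scaler = _fit_scaler(X_raw)
    X = scaler.transform(train.data)
    bad = [c for c, ok in zip(cols, np.isfinite(X).all(axis=0)) if not ok]
    if bad:
        raise ValueError(f"non-finite features after scaling: {bad}")

    oof = out_of_fold_predictions(X, y, hp, seed=seed, n_folds=n_folds)
    weights = search_weights(oof, y)
    oof_r2 = {name: float(r2_score(y, oof[name])) for name in BASE_LEARNERS}
    oof_r2["ensemble"] = float(r2_score(y, oof[list(BASE_LEARNERS)].to_numpy() @ weights))

    learners = {}
    for i, name in enumerate(BASE_LEARNERS):
        learner = _make_learner(name, hp[name], _derive_seed(seed, 200 + i))
        learner.fit(X, y)
        learners[name] = learner
    return EnsembleModel(
        learners=learners,
        weights=weights,
        scaler=scaler,
        feature_columns=cols,
        hyperparameters=hp,
        seed=seed,
        oof_r2=oof_r2,
    )


def grid_search_cv(
    train: FeatureTable,
    learner: str,
    param_grid: Mapping[str, Sequence],
    n_folds: int = 10,
    seed: int = 0,
    feature_columns: Sequence[str] | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search maximizing mean out-of-fold R^2.

    Fold assignment is deterministic in ``seed``.  Returns the best
    parameter dict and the full results table (one row per grid point
    with its mean and per-fold scores).
    """
    if learner not in BASE_LEARNERS:
        raise ValueError(f"learner must be one of {BASE_LEARNERS}")
    names = list(param_grid)
    if not names or any(len(v) == 0 for v in param_grid.values()):
        raise ValueError("empty parameter grid")
    cols = list(feature_columns) if feature_columns is not None else train.feature_columns
    scaler = _fit_scaler(train.data[cols])
    X = scaler.transform(train.data)
    y = train.data[TARGET_COLUMN].to_numpy(dtype=float)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=_derive_seed(seed, 1))
    folds = list(kf.split(X))

    records = []
    for values in product(*(param_grid[n] for n in names)):
        params = dict(DEFAULT_HYPERPARAMETERS[learner])
        params.update(dict(zip(names, values)))
        fold_scores = []
        for fold, (tr, va) in enumerate(folds):
            est = _make_learner(learner, params, _derive_seed(seed, 100 + fold))
            est.fit(X[tr], y[tr])
            fold_scores.append(r2_score(y[va], est.predict(X[va])))
        rec = dict(zip(names, values))
        rec["mean_cv_r2"] = float(np.mean(fold_scores))
        rec["std_cv_r2"] = float(np.std(fold_scores, ddof=1))
        records.append(rec)
    results = pd.DataFrame(records).sort_values("mean_cv_r2", ascending=False, kind="mergesort")
    best = results.iloc[0][names].to_dict()
    return best, results.reset_index(drop=True)
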