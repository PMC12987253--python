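"""Accuracy metrics and diagnostic analyses for biomass predictions.

Metrics::

    R^2  = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2
    RMSE = sqrt( (1/n) sum (y_i - yhat_i)^2 )
    MAE  = (1/n) sum |y_i - yhat_i|

Residuals follow the observed-minus-predicted sign convention, so
underestimation shows up as a *positive* residual.  Skewness and excess
kurtosis are the bias-uncorrected sample-moment forms (a normal sample
gives ~0 for both).  Grouping conventions: lower-closed, upper-open
intervals except the unbounded tails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble_model import EnsembleModel, SplitSpec, fit_ensemble, split_train_test
from .feature_table import (
    TARGET_COLUMN,
    FeatureTable,
    ImportanceRanking,
    impurity_importance,
)

ABS_RESIDUAL_CUTS = (0.1, 0.2, 0.3)
BIOMASS_INTERVALS = ((-np.inf, 1.0), (1.0, 1.3), (1.3, 1.6), (1.6, np.inf))
BIOMASS_INTERVAL_LABELS = ("low", "medium_low", "medium_high", "high")
MIN_STAGE_SAMPLES = 5


def _check_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be 1-D arrays of equal length")
    return observed, predicted


def regression_metrics(observed, predicted) -> dict[str, float]:
    """R^2, RMSE (kg m^-2) and MAE (kg m^-2) by direct formula evaluation."""
    y, yhat = _check_pair(observed, predicted)
    if len(y) < 2:
        raise ValueError("metrics need at least 2 samples")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        raise ValueError("constant observed values: R^2 is undefined")
    return {
        "R2": 1.0 - ss_res / ss_tot,
        "RMSE": float(np.sqrt(np.mean((y - yhat) ** 2))),
        "MAE": float(np.mean(np.abs(y - yhat))),
    }


def residual_diagnostics(observed, predicted) -> dict:
    """Residual distribution statistics and normal Q-Q coordinates.

    Returns residual mean/sd, sample skewness, excess kurtosis,
    absolute-residual bin proportions at cuts {0.1, 0.2, 0.3}, and the
    (theoretical, sample) normal quantile pairs for a Q-Q plot.
    """
    y, yhat = _check_pair(observed, predicted)
    if len(y) < 8:
        raise ValueError("residual diagnostics need at least 8 samples")
    r = y - yhat
    abs_r = np.abs(r)
    c1, c2, c3 = ABS_RESIDUAL_CUTS
    bins = {
        "lt_0.1": float(np.mean(abs_r < c1)),
        "0.1_0.2": float(np.mean((abs_r >= c1) & (abs_r < c2))),
        "0.2_0.3": float(np.mean((abs_r >= c2) & (abs_r < c3))),
        "gt_0.3": float(np.mean(abs_r >= c3)),
    }
    (theoretical, ordered), _ = stats.probplot(r, dist="norm")
    return {
        "residual_mean": float(np.mean(r)),
        "residual_sd": float(np.std(r, ddof=1)),
        "skewness": float(stats.skew(r, bias=True)),
        "kurtosis_excess": float(stats.kurtosis(r, fisher=True, bias=True)),
        "abs_residual_bins": bins,
        "qq_theoretical": theoretical,
        "qq_sample": ordered,
        "residuals": r,
    }


def _group_summary(residuals: np.ndarray) -> dict[str, float]:
    return {
        "n": int(len(residuals)),
        "mean_residual": float(np.mean(residuals)),
        "median_residual": float(np.median(residuals)),
        "mae": float(np.mean(np.abs(residuals))),
    }


def stratified_errors(observed, predicted, scheme: str = "quartiles") -> dict[str, dict]:
    """Residual summaries grouped by measured biomass.

    ``scheme="quartiles"`` groups by the quartiles of the observed
    biomass (Q1..Q4, lower-closed/upper-open with closed extremes);
    ``scheme="fixed_intervals"`` uses the <1.0 / 1.0-1.3 / 1.3-1.6 /
    >1.6 kg m^-2 intervals.  Empty groups are reported as absent.
    """
    y, yhat = _check_pair(observed, predicted)
    if len(y) < 8:
        raise ValueError("stratified errors need at least 8 samples")
    r = y - yhat
    groups: dict[str, dict] = {}
    if scheme == "quartiles":
        q1, q2, q3 = np.quantile(y, [0.25, 0.5, 0.75])
        edges = [(-np.inf, q1), (q1, q2), (q2, q3), (q3, np.inf)]
        labels = ("Q1", "Q2", "Q3", "Q4")
    elif scheme == "fixed_intervals":
        edges = list(BIOMASS_INTERVALS)
        labels = BIOMASS_INTERVAL_LABELS
    else:
        raise ValueError(f"unknown grouping scheme {scheme!r}")
    for (lo, hi), label in zip(edges, labels):
        mask = (y >= lo) & (y < hi) if np.isfinite(hi) else (y >= lo)
        if not mask.any():
            groups[label] = {"n": 0}
            continue
        groups[label] = _group_summary(r[mask])
    return groups


def stage_metrics(
    test: FeatureTable, model: EnsembleModel, min_samples: int = MIN_STAGE_SAMPLES
) -> pd.DataFrame:
    """Per-growth-stage metrics on test subsets.

    Stages with fewer than ``min_samples`` rows (or a constant target)
    are flagged low-confidence with absent R^2.
    """
    rows = []
    for stage, sub in test.data.groupby("stage", sort=True):
        y = sub[TARGET_COLUMN].to_numpy(dtype=float)
        yhat = model.predict(sub)
        rec: dict = {"stage": stage, "n": len(sub), "low_confidence": len(sub) < min_samples}
        if len(sub) >= 2 and np.ptp(y) > 0:
            rec.update(regression_metrics(y, yhat))
        else:
            rec.update({"R2": np.nan, "RMSE": np.nan, "MAE": np.nan, "low_confidence": True})
        rows.append(rec)
    return pd.DataFrame(rows)


FEATURE_COMBINATIONS = {
    "spectral_only": ("spectral",),
    "lidar_only": ("structural",),
    "fused": ("spectral", "structural", "geometry", "treatment", "interaction", "indicator"),
}


def feature_combination_study(
    table: FeatureTable,
    spec: SplitSpec,
    combos: Mapping[str, Sequence[str]] | None = None,
    hyperparameters: Mapping | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Train and evaluate the ensemble per feature-source combination.

    Every combination uses the identical train/test partition and root
    seed, so differences reflect the feature sets alone.
    """
    combos = dict(combos) if combos is not None else dict(FEATURE_COMBINATIONS)
    train, test = split_train_test(table, spec)
    rows = []
    for name, sources in combos.items():
        cols = table.features_by_source(sources)
        if not cols:
            raise ValueError(f"feature combination {name!r} selects no columns")
        model = fit_ensemble(train, feature_columns=cols, hyperparameters=hyperparameters, seed=seed)
        y = test.data[TARGET_COLUMN].to_numpy(dtype=float)
        metrics = regression_metrics(y, model.predict(test.data))
        rows.append({"combination": name, "n_features": len(cols), **metrics})
    return pd.DataFrame(rows)


def topk_ablation(
    table: FeatureTable,
    ranking: ImportanceRanking,
    spec: SplitSpec,
    ks: Sequence[int | str] = (5, 8, 10, 12, 15, "all"),
    hyperparameters: Mapping | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Retrain with the top-k ranked features under the fixed split.

    ``k`` values exceeding the feature count are clamped (and noted in
    the output); ``"all"`` uses the full ranked list.
    """
    order = ranking.ranked_features()
    train, test = split_train_test(table, spec)
    y = test.data[TARGET_COLUMN].to_numpy(dtype=float)
    rows = []
    for k in ks:
        if k == "all":
            cols, k_eff, clamped = order, len(order), False
        else:
            k_eff = min(int(k), len(order))
            clamped = k_eff != k
            cols = order[:k_eff]
        model = fit_ensemble(train, feature_columns=cols, hyperparameters=hyperparameters, seed=seed)
        metrics = regression_metrics(y, model.predict(test.data))
        rows.append({"k": str(k), "n_features": k_eff, "clamped": clamped, **metrics})
    return pd.DataFrame(rows)


def stagewise_importance(
    table: FeatureTable,
    forest_config: Mapping | None = None,
    seed: int = 0,
    min_rows: int = 20,
) -> pd.DataFrame:
    """Impurity importance recomputed per growth-stage subset.

    Columns are stages, rows are features; each column is normalized to
    sum to 1 for cross-stage comparison.  Stages with fewer than
    ``min_rows`` samples are reported as all-NaN columns.
    """
    stages = sorted(table.data["stage"].unique())
    if len(stages) < 2:
        raise ValueError("stagewise importance needs at least 2 stages")
    out = {}
    for stage in stages:
        sub = FeatureTable(
            data=table.data[table.data["stage"] == stage].reset_index(drop=True),
            provenance=dict(table.provenance),
        )
        if len(sub.data) < min_rows:
            out[stage] = pd.Series(np.nan, index=table.feature_columns)
            continue
        ranking = impurity_importance(sub, forest_config=forest_config, seed=seed)
        out[stage] = ranking.importance
    return pd.DataFrame(out)


@dataclass
class EvaluationReport:
    """Bundled evaluation of one model on one test set."""

    metrics: dict[str, float]
    diagnostics: dict
    quartile_groups: dict[str, dict]
    interval_groups: dict[str, dict]
    regression_line: dict[str, float]
    per_stage: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "metrics": self.metrics,
            "diagnostics": {
                k: v
                for k, v in self.diagnostics.items()
                if k not in ("qq_theoretical", "qq_sample", "residuals")
            },
            "quartile_groups": self.quartile_groups,
            "interval_groups": self.interval_groups,
            "regression_line": self.regression_line,
        }
        if self.per_stage is not None:
            d["per_stage"] = self.per_stage.to_dict(orient="records")
        return d


def evaluate_predictions(observed, predicted) -> EvaluationReport:
    """Full diagnostic report for one (observed, predicted) pair."""
    y, yhat = _check_pair(observed, predicted)
    slope, intercept = np.polyfit(y, yhat, 1)
    return EvaluationReport(
        metrics=regression_metrics(y, yhat),
        diagnostics=residual_diagnostics(y, yhat),
        quartile_groups=stratified_errors(y, yhat, "quartiles"),
        interval_groups=stratified_errors(y, yhat, "fixed_intervals"),
        regression_line={"slope": float(slope), "intercept": float(intercept)},
    )
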