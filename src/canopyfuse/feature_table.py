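"""Per-quadrat feature fusion, interaction features, impurity importance,
and cumulative-importance feature selection.

The importance measure is the variance-reduction (MSE) impurity
importance of a random forest regressor: for node t with N_t samples,

    I(t) = (1/N_t) sum_i (y_i - ybar_t)^2

a split of t into t_L, t_R on feature j reduces impurity by

    dI(t, j) = I(t) - (N_tL/N_t) I(t_L) - (N_tR/N_t) I(t_R)

the per-tree importance of j sums dI over the nodes split on j, and the
forest importance averages over trees and is normalized to sum to 1.
Note this sums the *per-node* reductions without the additional N_t/N
node-fraction weight some libraries apply; the per-node dI values are
exposed for direct verification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .pointcloud_features import HEIGHT_PERCENTILES, HEIGHT_STRATA, STRUCTURAL_FEATURE_NAMES, SparseROI
from .raster_features import VEGETATION_INDICES

META_COLUMNS = ("id", "batch_date", "stage", "fertilizer_level", "biomass")
TARGET_COLUMN = "biomass"

HEIGHT_PERCENTILE_COLS = tuple(f"Hq{p:02d}" for p in HEIGHT_PERCENTILES)
STRATUM_COLS = tuple(f"strata_{a:g}_{b:g}" for a, b in HEIGHT_STRATA)
INDEX_MEAN_COLS = tuple(f"{v}_mean" for v in VEGETATION_INDICES)


@dataclass
class FeatureTable:
    """Rows = quadrat samples; numeric feature columns + target + metadata.

    ``provenance`` maps every feature column to its source family
    ("spectral", "structural", "geometry", "treatment", "interaction",
    "indicator"), which the feature-combination study relies on.
    """

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data["id"].duplicated().any():
            dups = self.data.loc[self.data["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        unknown = [c for c in self.feature_columns if c not in self.provenance]
        if unknown:
            raise ValueError(f"feature columns without provenance: {unknown}")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    def features_by_source(self, sources: Sequence[str]) -> list[str]:
        return [c for c in self.feature_columns if self.provenance[c] in sources]

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    @property
    def y(self) -> pd.Series:
        return self.data[TARGET_COLUMN]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = {"provenance": self.provenance, "target": TARGET_COLUMN}
        path.with_suffix(".schema.json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".schema.json").read_text())
        return cls(data=data, provenance=sidecar["provenance"])


def fuse_features(
    rois,
    spectral: Mapping[str, Mapping[str, float]],
    structural: Mapping[str, Mapping[str, float] | SparseROI],
) -> FeatureTable:
    """Assemble one row per quadrat from the two extraction passes.

    Sparse ROIs (too few vegetation points for structural features) get
    their structural columns imputed with the across-quadrat median and
    are flagged by a ``structural_absent`` indicator column.
    """
    rows = []
    for roi in rois:
        row: dict = {
            "id": roi.id,
            "batch_date": roi.batch_date,
            "stage": roi.stage,
            "fertilizer_level": roi.fertilizer_level,
            "biomass": roi.biomass,
        }
        row.update(spectral[roi.id])
        struct = structural[roi.id]
        if isinstance(struct, SparseROI):
            row["structural_absent"] = 1.0
            for name in STRUCTURAL_FEATURE_NAMES:
                row[name] = np.nan
        else:
            row["structural_absent"] = 0.0
            row.update(struct)
        rows.append(row)
    data = pd.DataFrame(rows)
    for name in STRUCTURAL_FEATURE_NAMES:
        if data[name].isna().any():
            data[name] = data[name].fillna(data[name].median())

    provenance: dict[str, str] = {}
    sample_spec = next(iter(spectral.values()))
    for col in sample_spec:
        provenance[col] = (
            "geometry" if col in ("roi_area_m2", "count_valid_pixels", "count_total_pixels") else "spectral"
        )
    for col in STRUCTURAL_FEATURE_NAMES:
        provenance[col] = "structural"
    provenance["structural_absent"] = "indicator"
    data["fertilizer_level_feature"] = data["fertilizer_level"].astype(float)
    provenance["fertilizer_level_feature"] = "treatment"
    return FeatureTable(data=data, provenance=provenance)


def build_interaction_features(
    table: FeatureTable,
    structure_cols: Sequence[str] | None = None,
    spectral_cols: Sequence[str] | None = None,
) -> FeatureTable:
    """Append structure x spectrum product features.

    Default pairing (a_X_b naming): every height percentile and every
    vertical stratum proportion is crossed with every vegetation-index
    mean.  Products are the minimal faithful reading of "interaction":
    the joint term is zero whenever either factor vanishes.
    """
    height_cols = list(structure_cols) if structure_cols is not None else list(
        HEIGHT_PERCENTILE_COLS
    ) + list(STRATUM_COLS)
    index_cols = list(spectral_cols) if spectral_cols is not None else list(INDEX_MEAN_COLS)
    for col in height_cols + index_cols:
        if col not in table.data.columns:
            raise KeyError(f"interaction factor column missing: {col}")
    data = table.data.copy()
    provenance = dict(table.provenance)
    for a in height_cols:
        for b in index_cols:
            name = f"{a}_X_{b}"
            if name in data.columns:
                raise ValueError(f"interaction name collision: {name}")
            data[name] = data[a] * data[b]
            provenance[name] = "interaction"
    return FeatureTable(data=data, provenance=provenance)


@dataclass
class ImportanceRanking:
    """Normalized impurity importances with per-tree audit trail."""

    importance: pd.Series  # index = feature, normalized to sum 1, FI >= 0
    per_tree: pd.DataFrame  # rows = trees, cols = features (unnormalized FI_j^(m))
    n_trees: int

    def __post_init__(self) -> None:
        if (self.importance < -1e-12).any():
            raise ValueError("importances must be non-negative")
        total = self.importance.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"importances must be normalized; sum = {total}")

    def ranked_features(self) -> list[str]:
        """Features sorted by importance descending, ties by name."""
        df = self.importance.rename("fi").rename_axis("feature").reset_index()
        df = df.sort_values(["fi", "feature"], ascending=[False, True], kind="mergesort")
        return df["feature"].tolist()

    def to_csv(self, path: str | Path) -> Path:
        order = self.ranked_features()
        self.importance.loc[order].rename("importance").to_csv(path)
        return Path(path)


def tree_impurity_decreases(tree) -> pd.DataFrame:
    """Per-node impurity reductions dI(t, j) of one fitted sklearn tree.

    Returns a frame with columns node, feature (index), delta_i, where
    delta_i = I(t) - (N_L/N_t) I(t_L) - (N_R/N_t) I(t_R) computed from
    the tree's stored node impurities (variance of the target) and
    sample counts.
    """
    t = tree.tree_
    records = []
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        n_t = t.weighted_n_node_samples[node]
        n_l = t.weighted_n_node_samples[left]
        n_r = t.weighted_n_node_samples[right]
        delta = t.impurity[node] - (n_l / n_t) * t.impurity[left] - (n_r / n_t) * t.impurity[right]
        records.append({"node": node, "feature": int(t.feature[node]), "delta_i": float(delta)})
    return pd.DataFrame(records, columns=["node", "feature", "delta_i"])


def impurity_importance(
    table: FeatureTable,
    forest_config: Mapping | None = None,
    seed: int = 0,
) -> ImportanceRanking:
    """Variance-reduction feature importance of a random forest fit.

    ``forest_config`` overrides RandomForestRegressor keyword arguments
    (default 500 trees, sqrt feature subsampling).  Raises on a constant
    target, where every importance would be zero.
    """
    X, y = table.X, table.y
    if len(X) < 20:
        raise ValueError(f"importance estimation needs >= 20 training rows; got {len(X)}")
    if y.isna().any():
        raise ValueError("target contains missing values")
    if np.ptp(y.to_numpy()) == 0:
        raise ValueError("constant target: impurity importance is identically zero")
    config = {"n_estimators": 500, "max_features": "sqrt", "n_jobs": 1}
    if forest_config:
        config.update(forest_config)
    forest = RandomForestRegressor(random_state=seed, **config)
    forest.fit(X.to_numpy(), y.to_numpy())

    features = list(X.columns)
    per_tree = np.zeros((len(forest.estimators_), len(features)))
    for m, est in enumerate(forest.estimators_):
        decreases = tree_impurity_decreases(est)
        for fi, group in decreases.groupby("feature"):
            per_tree[m, fi] = group["delta_i"].sum()
    fi = per_tree.mean(axis=0)
    fi = np.clip(fi, 0.0, None)  # guard against -0.0 float dust
    total = fi.sum()
    if total <= 0:
        raise ValueError("all impurity reductions are zero; cannot normalize importances")
    return ImportanceRanking(
        importance=pd.Series(fi / total, index=features),
        per_tree=pd.DataFrame(per_tree, columns=features),
        n_trees=len(forest.estimators_),
    )


def select_by_cumulative_importance(
    ranking: ImportanceRanking, threshold: float = 0.95
) -> list[str]:
    """Shortest descending-importance prefix whose cumulative FI >= threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1]; got {threshold}")
    order = ranking.ranked_features()
    if not order:
        raise ValueError("empty importance ranking")
    cumulative = ranking.importance.loc[order].cumsum()
    n_keep = int(np.searchsorted(cumulative.to_numpy(), threshold - 1e-12) + 1)
    n_keep = min(n_keep, len(order))
    return order[:n_keep]
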