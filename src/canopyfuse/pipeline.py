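"""End-to-end pipeline: generate/load -> register -> extract -> fuse ->
select -> train -> evaluate, as one configured, logged, seeded run.

A run is described by a YAML/dict :class:`RunConfig` (schema-validated,
unknown keys rejected).  Every stage persists its outputs under the run
directory, and a machine-readable ``run_log.json`` records package
versions, derived seeds, and per-stage timings, so any stage can be
re-run from its persisted inputs with identical results.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__, io as cfio
from .containers import BAND_NAMES, CanopyPointCloud, QuadratROI, ReflectanceRaster
from .ensemble_model import (
    EnsembleModel,
    SplitSpec,
    fit_ensemble,
    split_train_test,
    _derive_seed,
)
from .evaluation import (
    evaluate_predictions,
    feature_combination_study,
    stage_metrics,
    topk_ablation,
)
from .feature_table import (
    FeatureTable,
    build_interaction_features,
    fuse_features,
    impurity_importance,
    select_by_cumulative_importance,
)
from .pointcloud_features import SparseROI, process_cloud, structural_features
from .raster_features import extract_spectral_features
from .registration import (
    ControlPointSet,
    PolynomialTransform,
    apply_transform,
    refine_and_select_order,
)
from .synthetic_scene import SceneConfig, generate_scene, write_scene


class SceneSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_quadrats: int = 60
    quadrat_side: float = 1.0
    pixel_size: float = 0.05
    biomass_range: tuple[float, float] = (0.3, 2.2)
    noise_sd_reflectance: float = 0.015
    noise_sd_height: float = 0.02
    shadow_fraction: float = 0.03
    saturation_fraction: float = 0.01
    outlier_count_per_quadrat: int = 2
    points_per_m2: float = 175.0
    stage_label: str = "branching"
    batch_date: str = "2025-08-13"
    cloud_shift: tuple[float, float] = (0.0, 0.0)


class InputsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    raster: str
    cloud: str
    rois: str
    control_points: Optional[str] = None


class PointCloudSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k_neighbors: int = 8
    sd_multiplier: float = 3.0
    cell_size: float = 0.25
    max_window: float = 2.0
    slope_tolerance: float = 0.15
    min_vegetation_points: int = 5


class RegistrationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rmse_threshold: Optional[float] = None  # default: one reference pixel


class SelectionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cumulative_threshold: float = 0.95
    n_estimators: int = 500


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    train_fraction: float = 0.85
    n_folds: int = 10
    hyperparameters: dict = Field(default_factory=dict)


class EvaluationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    combination_study: bool = False
    topk_ablation: bool = False
    per_stage: bool = True


class RunConfig(BaseModel):
    """Schema-validated run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    band_order: list[str]
    seed: int = 0
    output_dir: str = "runs/run"
    buffer_width: float = 0.075
    savi_l: float = 0.5
    scene: Optional[list[SceneSection] | SceneSection] = None
    inputs: Optional[InputsSection] = None
    pointcloud: PointCloudSection = Field(default_factory=PointCloudSection)
    registration: RegistrationSection = Field(default_factory=RegistrationSection)
    selection: SelectionSection = Field(default_factory=SelectionSection)
    model: ModelSection = Field(default_factory=ModelSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)

    @field_validator("band_order")
    @classmethod
    def _check_bands(cls, v):
        if list(v) != list(BAND_NAMES):
            raise ValueError(f"band_order must be {list(BAND_NAMES)}; got {v}")
        return v

    def scenes(self) -> list[SceneSection]:
        if self.scene is None:
            return []
        return self.scene if isinstance(self.scene, list) else [self.scene]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


class PipelineRun:
    """Mutable state of one pipeline execution."""

    def __init__(self, config: RunConfig, outdir: str | Path | None = None):
        self.config = config
        self.outdir = Path(outdir if outdir is not None else config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.log: dict = {
            "package_version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "stages": {},
        }
        self.raster: ReflectanceRaster | None = None
        self.cloud: CanopyPointCloud | None = None
        self.rois: list[QuadratROI] = []
        self.control_points: pd.DataFrame | None = None
        self.table: FeatureTable | None = None
        self.model: EnsembleModel | None = None
        self.selected: list[str] | None = None
        self._train = None
        self._test = None

    def _record(self, stage: str, started: float, **info) -> None:
        self.log["stages"][stage] = {"seconds": round(time.time() - started, 3), **info}
        (self.outdir / "run_log.json").write_text(json.dumps(self.log, indent=2))

    # ------------------------------------------------------------ stages

    def stage_generate(self) -> None:
        t0 = time.time()
        scenes = self.config.scenes()
        if not scenes:
            inputs = self.config.inputs
            if inputs is None:
                raise PipelineError("generate", ValueError("config has neither scene nor inputs"))
            self.raster = cfio.read_raster(inputs.raster)
            self.cloud = cfio.read_point_cloud(inputs.cloud)
            self.rois = cfio.read_rois(inputs.rois)
            if inputs.control_points:
                self.control_points = cfio.read_control_points(inputs.control_points)
            self._record("generate", t0, mode="loaded", n_rois=len(self.rois))
            return

        # multi-scene synthetic mode: each scene is one flight batch; all
        # share the root seed through documented derivation.
        rasters, clouds, all_rois, cps = [], [], [], []
        for i, section in enumerate(scenes):
            cfg = SceneConfig(
                **section.model_dump(), seed=_derive_seed(self.config.seed, 1000 + i)
            )
            scene = generate_scene(cfg)
            write_scene(scene, self.outdir / f"scene_{i:02d}")
            for roi in scene.quadrats:
                roi.buffer_width = self.config.buffer_width
            rasters.append(scene.raster)
            clouds.append(scene.cloud)
            all_rois.append(scene.quadrats)
            cps.append(scene.control_points)
        self._scenes = list(zip(rasters, clouds, all_rois, cps))
        self.raster, self.cloud, self.rois, self.control_points = (
            rasters[0],
            clouds[0],
            all_rois[0],
            cps[0],
        )
        self._record("generate", t0, mode="synthetic", n_scenes=len(scenes))

    def _register_one(self, cloud: CanopyPointCloud, cps: pd.DataFrame, raster) -> tuple[CanopyPointCloud, PolynomialTransform]:
        points = ControlPointSet.from_frame(cps)
        threshold = self.config.registration.rmse_threshold
        if threshold is None:
            threshold = raster.pixel_size
        transform = refine_and_select_order(points, rmse_threshold=threshold)
        aligned = cloud.copy()
        xy = apply_transform(transform, aligned.points[["x", "y"]].to_numpy())
        aligned.points["x"], aligned.points["y"] = xy[:, 0], xy[:, 1]
        return aligned, transform

    def stage_register(self) -> None:
        t0 = time.time()
        if not hasattr(self, "_scenes"):
            if self.control_points is None:
                self._record("register", t0, skipped=True)
                return
            self.cloud, transform = self._register_one(self.cloud, self.control_points, self.raster)
            transform.to_json(self.outdir / "transform.json")
            self._record(
                "register", t0, order=transform.order, rmse=transform.rmse, converged=transform.converged
            )
            return
        registered = []
        info = []
        for i, (raster, cloud, rois, cps) in enumerate(self._scenes):
            aligned, transform = self._register_one(cloud, cps, raster)
            transform.to_json(self.outdir / f"scene_{i:02d}" / "transform.json")
            registered.append((raster, aligned, rois, cps))
            info.append({"scene": i, "order": transform.order, "rmse": transform.rmse})
        self._scenes = registered
        self._record("register", t0, transforms=info)

    def stage_extract(self) -> None:
        t0 = time.time()
        pc = self.config.pointcloud
        scene_list = getattr(self, "_scenes", None) or [
            (self.raster, self.cloud, self.rois, None)
        ]
        spectral: dict[str, dict] = {}
        structural: dict[str, dict | SparseROI] = {}
        mask_reports: dict[str, dict] = {}
        rois_all: list[QuadratROI] = []
        for raster, cloud, rois, _ in scene_list:
            processed = process_cloud(
                cloud,
                k_neighbors=pc.k_neighbors,
                sd_multiplier=pc.sd_multiplier,
                cell_size=pc.cell_size,
                max_window=pc.max_window,
                slope_tolerance=pc.slope_tolerance,
            )
            for roi in rois:
                roi.buffer_width = self.config.buffer_width
                feats, report = extract_spectral_features(raster, roi, savi_l=self.config.savi_l)
                spectral[roi.id] = feats
                mask_reports[roi.id] = report.to_dict()
                structural[roi.id] = structural_features(
                    processed, roi, min_vegetation_points=pc.min_vegetation_points
                )
                rois_all.append(roi)
        (self.outdir / "mask_reports.json").write_text(json.dumps(mask_reports, indent=2))
        self._extracted = (rois_all, spectral, structural)
        n_sparse = sum(1 for v in structural.values() if isinstance(v, SparseROI))
        self._record("extract", t0, n_rois=len(rois_all), n_sparse_rois=n_sparse)

    def stage_fuse(self) -> None:
        t0 = time.time()
        rois, spectral, structural = self._extracted
        table = fuse_features(rois, spectral, structural)
        table = build_interaction_features(table)
        table.to_csv(self.outdir / "feature_table.csv")
        self.table = table
        self._record("fuse", t0, n_rows=len(table.data), n_features=len(table.feature_columns))

    def stage_train(self) -> None:
        t0 = time.time()
        spec = SplitSpec(
            train_fraction=self.config.model.train_fraction,
            seed=_derive_seed(self.config.seed, 2),
            n_folds=self.config.model.n_folds,
        )
        train, test = split_train_test(self.table, spec)
        ranking = impurity_importance(
            train,
            forest_config={"n_estimators": self.config.selection.n_estimators},
            seed=_derive_seed(self.config.seed, 3),
        )
        ranking.to_csv(self.outdir / "importance_ranking.csv")
        selected = select_by_cumulative_importance(
            ranking, threshold=self.config.selection.cumulative_threshold
        )
        (self.outdir / "selected_features.json").write_text(json.dumps(selected, indent=2))
        model = fit_ensemble(
            train,
            feature_columns=selected,
            hyperparameters=self.config.model.hyperparameters,
            seed=_derive_seed(self.config.seed, 4),
            n_folds=self.config.model.n_folds,
        )
        model.save(self.outdir / "model")
        self.model, self.selected = model, selected
        self._train, self._test = train, test
        self._split_spec = spec
        self._record(
            "train",
            t0,
            n_train=len(train.data),
            n_test=len(test.data),
            n_selected=len(selected),
            weights=dict(zip(("RF", "ET", "HGB"), model.weights.tolist())),
            oof_r2=model.oof_r2,
        )

    def stage_evaluate(self) -> None:
        t0 = time.time()
        test = self._test
        y = test.data["biomass"].to_numpy(dtype=float)
        yhat = self.model.predict(test.data)
        report = evaluate_predictions(y, yhat)
        if self.config.evaluation.per_stage and test.data["stage"].nunique() >= 1:
            report.per_stage = stage_metrics(test, self.model)
        payload = report.to_dict()
        if self.config.evaluation.combination_study:
            study = feature_combination_study(
                self.table,
                self._split_spec,
                hyperparameters=self.config.model.hyperparameters,
                seed=_derive_seed(self.config.seed, 4),
            )
            study.to_csv(self.outdir / "feature_combinations.csv", index=False)
            payload["feature_combinations"] = study.to_dict(orient="records")
        if self.config.evaluation.topk_ablation:
            ranking = impurity_importance(
                self._train,
                forest_config={"n_estimators": self.config.selection.n_estimators},
                seed=_derive_seed(self.config.seed, 3),
            )
            ablation = topk_ablation(
                self.table,
                ranking,
                self._split_spec,
                hyperparameters=self.config.model.hyperparameters,
                seed=_derive_seed(self.config.seed, 4),
            )
            ablation.to_csv(self.outdir / "topk_ablation.csv", index=False)
            payload["topk_ablation"] = ablation.to_dict(orient="records")
        (self.outdir / "evaluation_report.json").write_text(json.dumps(payload, indent=2))
        predictions = pd.DataFrame(
            {"id": test.data["id"], "observed": y, "predicted_biomass": yhat}
        )
        predictions.to_csv(self.outdir / "predictions.csv", index=False)
        self.report = report
        self._record("evaluate", t0, **report.metrics)


STAGES = ("generate", "register", "extract", "fuse", "train", "evaluate")


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineRun:
    """Execute all stages in order; a stage failure halts the run with the
    stage name while earlier artifacts remain on disk."""
    run = PipelineRun(config, outdir=outdir)
    for stage in STAGES:
        try:
            getattr(run, f"stage_{stage}")()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
            raise PipelineError(stage, exc) from exc
    return run
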