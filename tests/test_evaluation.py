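"""Metrics, residual diagnostics, stratified errors, and study harnesses."""

import numpy as np
import pandas as pd
import pytest

from canopyfuse.ensemble_model import SplitSpec, fit_ensemble, split_train_test
from canopyfuse.evaluation import (
    evaluate_predictions,
    feature_combination_study,
    regression_metrics,
    residual_diagnostics,
    stage_metrics,
    stagewise_importance,
    stratified_errors,
    topk_ablation,
)
from canopyfuse.feature_table import FeatureTable, impurity_importance

from conftest import FAST_HYPERPARAMETERS


def _multisource_table(n=120, seed=0, spectral_signal=0.5, structural_signal=0.5):
    rng = np.random.default_rng(seed)
    b = rng.uniform(0.4, 2.0, n)
    df = pd.DataFrame(
        {
            "NDVI_mean": b * spectral_signal + rng.normal(scale=0.05, size=n),
            "GNDVI_mean": b * spectral_signal * 0.8 + rng.normal(scale=0.05, size=n),
            "Hq50": b * structural_signal + rng.normal(scale=0.05, size=n),
            "Hmean": b * structural_signal * 0.9 + rng.normal(scale=0.05, size=n),
            "noise": rng.normal(size=n),
        }
    )
    df["id"] = [f"s{i}" for i in range(n)]
    df["batch_date"] = ""
    df["stage"] = np.where(np.arange(n) % 2 == 0, "branching", "bud")
    df["fertilizer_level"] = 1.0
    df["biomass"] = b
    prov = {
        "NDVI_mean": "spectral",
        "GNDVI_mean": "spectral",
        "Hq50": "structural",
        "Hmean": "structural",
        "noise": "geometry",
    }
    return FeatureTable(data=df, provenance=prov)


class TestRegressionMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        m = regression_metrics(y, y)
        assert m == {"R2": 1.0, "RMSE": 0.0, "MAE": 0.0}

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m["R2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_case(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([1.1, 1.9, 3.2])
        m = regression_metrics(y, yhat)
        assert m["RMSE"] == pytest.approx(np.sqrt(0.06 / 3), abs=1e-12)
        assert m["MAE"] == pytest.approx(0.4 / 3, abs=1e-12)
        assert m["R2"] == pytest.approx(1 - 0.06 / 2.0, abs=1e-12)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regression_metrics(np.ones(5), np.arange(5.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics(np.ones(3), np.ones(4))


class TestResidualDiagnostics:
    def test_symmetric_residuals_have_zero_skew(self):
        y = np.arange(10.0)
        r = np.array([-0.4, -0.3, -0.2, -0.1, 0.0, 0.0, 0.1, 0.2, 0.3, 0.4])
        d = residual_diagnostics(y, y - r)
        assert d["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert d["residual_mean"] == pytest.approx(0.0, abs=1e-12)

    def test_normal_sample_moments_near_zero(self):
        rng = np.random.default_rng(1)
        r = rng.normal(size=100_000)
        d = residual_diagnostics(r, np.zeros_like(r))
        se_skew = np.sqrt(6 / len(r))
        se_kurt = np.sqrt(24 / len(r))
        assert abs(d["skewness"]) < 3 * se_skew
        assert abs(d["kurtosis_excess"]) < 3 * se_kurt

    def test_small_residuals_land_in_first_bin(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(1, 2, 20)
        d = residual_diagnostics(y, y + rng.uniform(-0.09, 0.09, 20))
        assert d["abs_residual_bins"]["lt_0.1"] == 1.0
        assert sum(d["abs_residual_bins"].values()) == pytest.approx(1.0)

    def test_bin_proportions_match_hand_count(self):
        y = np.zeros(8)
        yhat = -np.array([0.05, 0.05, 0.15, 0.15, 0.25, 0.25, 0.35, 0.45])
        d = residual_diagnostics(y, yhat)
        assert d["abs_residual_bins"] == {
            "lt_0.1": 0.25,
            "0.1_0.2": 0.25,
            "0.2_0.3": 0.25,
            "gt_0.3": 0.25,
        }


class TestStratifiedErrors:
    def test_unbiased_predictions_center_every_quartile(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0.5, 2.0, 4000)
        yhat = y + rng.normal(scale=0.05, size=4000)
        groups = stratified_errors(y, yhat, "quartiles")
        for g in groups.values():
            assert abs(g["median_residual"]) < 0.01

    def test_shrinkage_signs_in_extreme_quartiles(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(0.5, 2.0, 500)
        yhat = y.mean() + 0.5 * (y - y.mean())
        groups = stratified_errors(y, yhat, "quartiles")
        assert groups["Q4"]["mean_residual"] > 0
        assert groups["Q1"]["mean_residual"] < 0

    def test_eight_samples_two_per_quartile(self):
        y = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        groups = stratified_errors(y, y, "quartiles")
        assert [groups[q]["n"] for q in ("Q1", "Q2", "Q3", "Q4")] == [2, 2, 2, 2]

    def test_quartiles_partition_the_sample(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(0.3, 2.2, 123)
        groups = stratified_errors(y, y + 0.01, "quartiles")
        assert sum(g["n"] for g in groups.values()) == 123

    def test_fixed_intervals_with_empty_group(self):
        y = np.array([0.5, 0.6, 0.7, 0.8, 1.1, 1.2, 1.25, 1.7])
        groups = stratified_errors(y, y, "fixed_intervals")
        assert groups["low"]["n"] == 4
        assert groups["medium_low"]["n"] == 3
        assert groups["medium_high"] == {"n": 0}
        assert groups["high"]["n"] == 1


class TestModelStudies:
    def test_single_stage_metrics_equal_global(self):
        table = _multisource_table(n=80, seed=6)
        table.data["stage"] = "branching"
        train, test = split_train_test(table, SplitSpec(seed=0))
        model = fit_ensemble(train, hyperparameters=FAST_HYPERPARAMETERS, seed=0)
        per_stage = stage_metrics(test, model)
        y = test.data["biomass"].to_numpy()
        global_m = regression_metrics(y, model.predict(test.data))
        assert len(per_stage) == 1
        assert per_stage.iloc[0]["R2"] == pytest.approx(global_m["R2"], abs=1e-12)

    def test_noisier_stage_scores_lower(self):
        rng = np.random.default_rng(7)
        n = 160
        b = rng.uniform(0.4, 2.0, n)
        stage = np.where(np.arange(n) < n // 2, "clean", "noisy")
        noise = np.where(stage == "clean", 0.03, 0.5)
        df = pd.DataFrame({"f0": b + rng.normal(scale=noise), "f1": rng.normal(size=n)})
        df["id"] = [f"s{i}" for i in range(n)]
        df["batch_date"] = ""
        df["stage"] = stage
        df["fertilizer_level"] = 1.0
        df["biomass"] = b
        table = FeatureTable(data=df, provenance={"f0": "spectral", "f1": "spectral"})
        train, test = split_train_test(table, SplitSpec(seed=1))
        model = fit_ensemble(train, hyperparameters=FAST_HYPERPARAMETERS, seed=0)
        per_stage = stage_metrics(test, model).set_index("stage")
        assert per_stage.loc["noisy", "R2"] < per_stage.loc["clean", "R2"]

    def test_tiny_stage_flagged_without_r2(self):
        table = _multisource_table(n=80, seed=8)
        table.data.loc[0, "stage"] = "flowering"
        train, test = split_train_test(table, SplitSpec(seed=3))
        # force the lone flowering row into the test set
        test.data.loc[len(test.data)] = table.data.iloc[0]
        model = fit_ensemble(train, hyperparameters=FAST_HYPERPARAMETERS, seed=0)
        per_stage = stage_metrics(test, model).set_index("stage")
        if "flowering" in per_stage.index:
            row = per_stage.loc["flowering"]
            assert bool(row["low_confidence"])
            assert np.isnan(row["R2"])

    def test_fused_at_least_single_sources_and_shuffled_spectral_collapses(self):
        table = _multisource_table(n=150, seed=9)
        spec = SplitSpec(seed=2)
        study = feature_combination_study(
            table, spec, hyperparameters=FAST_HYPERPARAMETERS, seed=0
        ).set_index("combination")
        assert study.loc["fused", "R2"] >= max(
            study.loc["spectral_only", "R2"], study.loc["lidar_only", "R2"]
        ) - 0.05
        # destroyed-signal control: shuffle spectral columns against the target
        rng = np.random.default_rng(0)
        broken = table.data.copy()
        for col in ("NDVI_mean", "GNDVI_mean"):
            broken[col] = rng.permutation(broken[col].to_numpy())
        table_b = FeatureTable(data=broken, provenance=dict(table.provenance))
        study_b = feature_combination_study(
            table_b, spec, hyperparameters=FAST_HYPERPARAMETERS, seed=0
        ).set_index("combination")
        assert study_b.loc["spectral_only", "R2"] < 0.2

    def test_identical_feature_sets_identical_metrics(self):
        table = _multisource_table(n=100, seed=10)
        spec = SplitSpec(seed=4)
        combos = {"a": ("spectral",), "b": ("spectral",)}
        study = feature_combination_study(
            table, spec, combos=combos, hyperparameters=FAST_HYPERPARAMETERS, seed=0
        ).set_index("combination")
        assert study.loc["a", "R2"] == pytest.approx(study.loc["b", "R2"], abs=1e-12)

    def test_topk_plateau_and_identity_at_all(self):
        table = _multisource_table(n=150, seed=11)
        train, test = split_train_test(table, SplitSpec(seed=5))
        ranking = impurity_importance(
            train, forest_config={"n_estimators": 60, "max_features": None}, seed=0
        )
        spec = SplitSpec(seed=5)
        ablation = topk_ablation(
            table, ranking, spec, ks=(1, 4, "all"), hyperparameters=FAST_HYPERPARAMETERS, seed=0
        ).set_index("k")
        # the four informative features carry the signal; k=1 is strictly worse
        assert ablation.loc["1", "R2"] < ablation.loc["all", "R2"]
        assert ablation.loc["4", "R2"] > ablation.loc["all", "R2"] - 0.1
        # k = all retrains with every ranked feature under the same split
        model = fit_ensemble(
            train, feature_columns=ranking.ranked_features(),
            hyperparameters=FAST_HYPERPARAMETERS, seed=0,
        )
        y = test.data["biomass"].to_numpy()
        direct = regression_metrics(y, model.predict(test.data))
        assert ablation.loc["all", "R2"] == pytest.approx(direct["R2"], abs=1e-12)

    def test_topk_clamps_oversized_k(self):
        table = _multisource_table(n=100, seed=12)
        train, _ = split_train_test(table, SplitSpec(seed=6))
        ranking = impurity_importance(train, forest_config={"n_estimators": 30}, seed=0)
        ablation = topk_ablation(
            table, ranking, SplitSpec(seed=6), ks=(500,),
            hyperparameters=FAST_HYPERPARAMETERS, seed=0,
        )
        assert ablation.iloc[0]["clamped"]
        assert ablation.iloc[0]["n_features"] == len(table.feature_columns)

    def test_stagewise_importance_finds_stage_specific_signal(self):
        rng = np.random.default_rng(13)
        n = 160
        b = rng.uniform(0.4, 2.0, n)
        stage = np.where(np.arange(n) < n // 2, "early", "late")
        spectral = np.where(stage == "early", b, rng.uniform(0.4, 2.0, n))
        structural = np.where(stage == "late", b, rng.uniform(0.4, 2.0, n))
        df = pd.DataFrame({"NDVI_mean": spectral, "Hq50": structural})
        df["id"] = [f"s{i}" for i in range(n)]
        df["batch_date"] = ""
        df["stage"] = stage
        df["fertilizer_level"] = 1.0
        df["biomass"] = b
        table = FeatureTable(
            data=df, provenance={"NDVI_mean": "spectral", "Hq50": "structural"}
        )
        imp = stagewise_importance(
            table, forest_config={"n_estimators": 60, "max_features": None}, seed=0
        )
        assert imp["early"].sum() == pytest.approx(1.0, abs=1e-9)
        assert imp["late"].sum() == pytest.approx(1.0, abs=1e-9)
        assert imp.loc["NDVI_mean", "early"] > imp.loc["Hq50", "early"]
        assert imp.loc["Hq50", "late"] > imp.loc["NDVI_mean", "late"]

    def test_evaluate_predictions_bundles_consistently(self):
        rng = np.random.default_rng(14)
        y = rng.uniform(0.5, 2.0, 60)
        yhat = y + rng.normal(scale=0.1, size=60)
        report = evaluate_predictions(y, yhat)
        assert report.metrics["R2"] == regression_metrics(y, yhat)["R2"]
        assert sum(g["n"] for g in report.quartile_groups.values()) == 60
        d = report.to_dict()
        assert "qq_theoretical" not in d["diagnostics"]
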