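"""Spectral extraction: pixel selection, masking cascade, statistics, indices."""

import numpy as np
import pytest
from shapely.geometry import box

from canopyfuse.containers import BAND_NAMES, QuadratROI, ReflectanceRaster
from canopyfuse.raster_features import (
    DegenerateROIError,
    EmptyROIError,
    apply_mask_cascade,
    band_statistics,
    clip_and_buffer,
    extract_spectral_features,
    raster_histogram_features,
    vegetation_indices,
)
from canopyfuse._stats import histogram_features

from conftest import make_uniform_raster


def _roi(poly, buffer=0.05, **kw):
    return QuadratROI(id="t1", polygon=poly, buffer_width=buffer, **kw)


def _raster_from_pixels(pixel_bands: np.ndarray, pixel_size=1.0):
    """(5, rows, cols) array -> raster with origin at (0, rows*ps)."""
    return ReflectanceRaster(
        data=pixel_bands, origin=(0.0, pixel_bands.shape[1] * pixel_size), pixel_size=pixel_size
    )


class TestClipAndBuffer:
    def test_one_meter_roi_with_5cm_buffer_selects_18x18(self):
        raster = make_uniform_raster({b: 0.4 for b in BAND_NAMES}, shape=(20, 20))
        roi = _roi(box(0, 0, 1, 1), buffer=0.05)
        rows, cols = clip_and_buffer(raster, roi)
        assert len(rows) == 18 * 18  # centers in (0.05, 0.95)^2

    def test_zero_buffer_exact_tiling_selects_all(self):
        raster = make_uniform_raster({b: 0.4 for b in BAND_NAMES}, shape=(20, 20))
        roi = _roi(box(0, 0, 1, 1), buffer=0.0)
        rows, cols = clip_and_buffer(raster, roi)
        assert len(rows) == 400

    def test_roi_outside_raster_raises_empty(self):
        raster = make_uniform_raster({b: 0.4 for b in BAND_NAMES}, shape=(20, 20))
        with pytest.raises(EmptyROIError, match="t1"):
            clip_and_buffer(raster, _roi(box(50, 50, 51, 51)))


class TestMaskCascade:
    def _toy_raster(self):
        """3x3 ROI: 7 identical clean pixels, one shadow, one saturated.

        Clean pixels share identical band values so the percentile
        bounds coincide with the data and the strict-inequality quantile
        stage removes nothing.
        """
        clean = {"Blue": 0.05, "Green": 0.2, "Red": 0.1, "RedEdge": 0.3, "NIR": 0.5}
        data = np.stack([np.full((3, 3), clean[b]) for b in BAND_NAMES]).astype(np.float32)
        nir = BAND_NAMES.index("NIR")
        data[nir, 0, 0] = 0.02  # shadow: NDVI still high? no -> make NDVI pass
        data[BAND_NAMES.index("Red"), 0, 0] = 0.001  # keeps NDVI >= 0.2 despite low NIR
        data[nir, 2, 2] = 0.97  # saturated
        return _raster_from_pixels(data)

    def test_toy_counts_match_hand_enumeration(self):
        raster = self._toy_raster()
        roi = _roi(box(0, 0, 3, 3), buffer=0.0)
        pixels = clip_and_buffer(raster, roi)
        valid, report = apply_mask_cascade(pixels, raster, roi_id="toy")
        assert report.n_total == 9
        assert report.n_nonveg == 0
        assert report.n_shadow == 1
        assert report.n_saturated == 1
        assert report.n_valid == 7
        assert all(v == 0 for v in report.n_quantile_excluded.values())

    def test_uniform_pixels_survive_every_stage(self):
        raster = make_uniform_raster(
            {"Blue": 0.05, "Green": 0.2, "Red": 0.1, "RedEdge": 0.3, "NIR": 0.5}, shape=(10, 10)
        )
        roi = _roi(box(0.0, 0.0, 0.5, 0.5), buffer=0.0)
        pixels = clip_and_buffer(raster, roi)
        valid, report = apply_mask_cascade(pixels, raster)
        assert report.n_valid == report.n_total == 100

    def test_bare_soil_roi_raises_empty(self):
        # NDVI = (0.21 - 0.19) / 0.40 = 0.05 < 0.20 everywhere
        raster = make_uniform_raster(
            {"Blue": 0.1, "Green": 0.15, "Red": 0.19, "RedEdge": 0.2, "NIR": 0.21}, shape=(10, 10)
        )
        roi = _roi(box(0.0, 0.0, 0.5, 0.5), buffer=0.0)
        with pytest.raises(EmptyROIError):
            apply_mask_cascade(clip_and_buffer(raster, roi), raster)

    def test_pointwise_stages_idempotent_and_quantile_trims_extremes(self):
        rng = np.random.default_rng(0)
        data = np.stack(
            [
                np.full((20, 20), v) + rng.normal(0, 0.01, (20, 20))
                for v in (0.05, 0.2, 0.1, 0.3, 0.5)
            ]
        ).astype(np.float32)
        raster = _raster_from_pixels(data, pixel_size=0.05)
        roi = _roi(box(0, 0, 1, 1), buffer=0.0)
        valid, report = apply_mask_cascade(clip_and_buffer(raster, roi), raster)
        # per-band trim flags ~2% of 400 pixels per band (strict bounds)
        for b in BAND_NAMES:
            assert 1 <= report.n_quantile_excluded[b] <= 12
        # the three pointwise stages remove nothing on the survivors
        _, report2 = apply_mask_cascade(valid, raster)
        assert report2.n_nonveg == report2.n_shadow == report2.n_saturated == 0


class TestBandStatistics:
    def test_constant_band_collapses_all_statistics(self):
        raster = make_uniform_raster({b: 0.4 for b in BAND_NAMES}, shape=(10, 10))
        roi = _roi(box(0.0, 0.0, 0.5, 0.5), buffer=0.0)
        stats = band_statistics(clip_and_buffer(raster, roi), raster)
        for b in BAND_NAMES:
            for stat in ("mean", "median", "min", "max", "p10", "p50", "p90"):
                assert stats[f"{b}_{stat}"] == pytest.approx(0.4, abs=1e-7)
            assert stats[f"{b}_std"] == 0.0

    def test_four_point_set_matches_sort_based_oracle(self):
        values = np.array([0.1, 0.2, 0.3, 0.4], dtype=np.float32)
        data = np.stack([values.reshape(1, 4)] * 5)
        raster = _raster_from_pixels(data)
        pixels = (np.zeros(4, dtype=int), np.arange(4))
        stats = band_statistics(pixels, raster)
        assert stats["NIR_median"] == pytest.approx(0.25, abs=1e-7)
        # oracle: linear interpolation at index q*(n-1) on the sorted values
        s = np.sort(values.astype(float))
        for q in range(10, 100, 10):
            idx = q / 100 * 3
            lo, frac = int(np.floor(idx)), idx - int(np.floor(idx))
            expected = s[lo] + frac * (s[min(lo + 1, 3)] - s[lo])
            assert stats[f"NIR_p{q}"] == pytest.approx(expected, abs=1e-7)
        assert stats["NIR_std"] == pytest.approx(np.std(values.astype(float), ddof=1), abs=1e-9)

    def test_percentile_chain_is_monotone(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0.1, 0.6, size=(5, 8, 8)).astype(np.float32)
        raster = _raster_from_pixels(data)
        rows, cols = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        stats = band_statistics((rows.ravel(), cols.ravel()), raster)
        for b in BAND_NAMES:
            chain = [stats[f"{b}_min"]] + [stats[f"{b}_p{q}"] for q in range(10, 100, 10)]
            chain.append(stats[f"{b}_max"])
            assert all(a <= x + 1e-12 for a, x in zip(chain, chain[1:]))

    def test_single_pixel_is_degenerate(self):
        raster = make_uniform_raster({b: 0.4 for b in BAND_NAMES}, shape=(4, 4))
        with pytest.raises(DegenerateROIError):
            band_statistics((np.array([0]), np.array([0])), raster)


class TestHistogramFeatures:
    def test_point_mass_has_unit_frequency_zero_width(self):
        hf = histogram_features(np.full(50, 0.3))
        assert hf.peak_frequency == 1.0
        assert hf.distribution_width == 0.0
        assert hf.peak_location == pytest.approx(0.3)

    def test_equal_bimodal_ties_break_to_lower_bin(self):
        # two clusters with equal counts at the extremes of the range
        values = np.concatenate([np.full(10, 0.1), np.full(10, 0.9)])
        hf = histogram_features(values)
        assert hf.peak_location < 0.5  # lower-valued modal bin chosen

    def test_uniform_sample_is_flat_and_wide(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0.0, 1.0, 200_000)
        hf = histogram_features(values)
        assert hf.peak_frequency == pytest.approx(1 / 50, rel=0.12)
        assert hf.distribution_width == pytest.approx(values.max() - values.min(), rel=0.05)

    def test_band_histogram_keys_present(self):
        raster = make_uniform_raster({b: 0.4 for b in BAND_NAMES}, shape=(10, 10))
        roi = _roi(box(0.0, 0.0, 0.5, 0.5), buffer=0.0)
        out = raster_histogram_features(clip_and_buffer(raster, roi), raster)
        assert out["NIR_peak_frequency"] == 1.0


class TestVegetationIndices:
    def test_single_pixel_matches_hand_arithmetic(self):
        vals = {"NIR": 0.5, "Red": 0.1, "Blue": 0.05, "Green": 0.2, "RedEdge": 0.3}
        raster = make_uniform_raster(vals, shape=(2, 2))
        pixels = (np.array([0]), np.array([0]))
        means, dropped = vegetation_indices(pixels, raster, savi_l=0.5)
        nir, red, blue, green, rededge = 0.5, 0.1, 0.05, 0.2, 0.3
        assert means["NDVI_mean"] == pytest.approx((nir - red) / (nir + red), abs=1e-7)
        assert means["NDRE_mean"] == pytest.approx((nir - rededge) / (nir + rededge), abs=1e-7)
        assert means["GNDVI_mean"] == pytest.approx((nir - green) / (nir + green), abs=1e-7)
        assert means["MSR_mean"] == pytest.approx(
            (nir / red - 1) / (nir / red + 1), abs=1e-7
        )
        assert means["EVI_mean"] == pytest.approx(
            2.5 * (nir - red) / (nir + 6 * red - 7.5 * blue + 1), abs=1e-7
        )
        assert means["SAVI_mean"] == pytest.approx(
            1.5 * (nir - red) / (nir + red + 0.5), abs=1e-7
        )
        assert all(v == 0 for v in dropped.values())

    def test_nir_equal_red_gives_zero_ndvi_and_msr(self):
        raster = make_uniform_raster(
            {"NIR": 0.3, "Red": 0.3, "Blue": 0.05, "Green": 0.2, "RedEdge": 0.25}, shape=(4, 4)
        )
        pixels = (np.array([0, 1]), np.array([0, 1]))
        means, _ = vegetation_indices(pixels, raster)
        assert means["NDVI_mean"] == pytest.approx(0.0, abs=1e-7)
        assert means["MSR_mean"] == pytest.approx(0.0, abs=1e-7)

    def test_zero_red_saturates_ndvi_at_one(self):
        raster = make_uniform_raster(
            {"NIR": 0.5, "Red": 0.0, "Blue": 0.05, "Green": 0.2, "RedEdge": 0.3}, shape=(4, 4)
        )
        means, _ = vegetation_indices((np.array([0]), np.array([0])), raster)
        assert means["NDVI_mean"] == pytest.approx(1.0, abs=1e-7)


class TestFullExtraction:
    def test_permutation_invariance_of_features(self, small_scene):
        roi = small_scene.quadrats[0]
        pixels = clip_and_buffer(small_scene.raster, roi)
        valid, _ = apply_mask_cascade(pixels, small_scene.raster, roi.id)
        stats = band_statistics(valid, small_scene.raster)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(valid[0]))
        shuffled = (valid[0][order], valid[1][order])
        stats2 = band_statistics(shuffled, small_scene.raster)
        for k, v in stats.items():
            assert stats2[k] == pytest.approx(v, abs=1e-12)

    def test_roi_ndvi_mean_monotone_in_cover(self, small_scene):
        ndvi, cover = [], []
        for roi, c in zip(small_scene.quadrats, small_scene.true_params["cover_fraction"]):
            feats, _ = extract_spectral_features(small_scene.raster, roi)
            ndvi.append(feats["NDVI_mean"])
            cover.append(c)
        order = np.argsort(cover)
        from scipy.stats import spearmanr

        assert spearmanr(ndvi, cover).statistic > 0.98

    def test_geometry_counts_consistent(self, small_scene):
        roi = small_scene.quadrats[0]
        feats, report = extract_spectral_features(small_scene.raster, roi)
        assert feats["count_valid_pixels"] == report.n_valid
        assert feats["count_total_pixels"] == report.n_total
        assert feats["roi_area_m2"] == pytest.approx(roi.buffered().area)
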