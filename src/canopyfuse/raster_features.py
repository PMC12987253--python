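"""Quadrat-scale spectral features from reflectance rasters.

For each inward-buffered quadrat ROI the pipeline:

1. selects pixels whose centers fall inside the buffered polygon,
2. runs the masking cascade — vegetation test (NDVI < 0.20), shadow test
   (NIR < 0.05), saturation test (any band > 0.95), then per-band
   1st/99th-percentile trimming with strict inequalities,
3. computes per-band statistics (mean, median, sample std, min, max,
   10th-90th percentiles), histogram-shape features, the six vegetation
   index means (NDVI, NDRE, GNDVI, MSR, EVI, SAVI) and geometric counts.

The cascade order is fixed.  The three threshold stages are pointwise
and therefore idempotent; the percentile trim is rank-based, so on a
non-degenerate sample a second pass would trim again — the cascade is
applied exactly once per ROI (see docs/methods.md for the convention).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import shapely

from ._stats import histogram_features, percentile, sample_std
from .containers import BAND_NAMES, QuadratROI, ReflectanceRaster

NDVI_THRESHOLD = 0.20
NIR_SHADOW_THRESHOLD = 0.05
SATURATION_THRESHOLD = 0.95
QUANTILE_LOW = 1.0
QUANTILE_HIGH = 99.0
DEFAULT_SAVI_L = 0.5

VEGETATION_INDICES = ("NDVI", "NDRE", "GNDVI", "MSR", "EVI", "SAVI")
BAND_STAT_NAMES = ("mean", "median", "std", "min", "max") + tuple(f"p{q}" for q in range(10, 100, 10))
HISTOGRAM_STAT_NAMES = ("peak_location", "peak_frequency", "distribution_width")


class EmptyROIError(ValueError):
    """Raised when an ROI yields no usable pixels."""

    def __init__(self, roi_id: str, message: str):
        self.roi_id = roi_id
        super().__init__(f"ROI {roi_id}: {message}")


class DegenerateROIError(ValueError):
    """Raised when an ROI has too few valid pixels for the requested statistics."""


@dataclass
class PixelMaskReport:
    """Per-stage tallies of the masking cascade for one ROI."""

    n_total: int
    n_nonveg: int
    n_shadow: int
    n_saturated: int
    n_quantile_excluded: dict[str, int]
    n_valid: int
    n_index_denominator_dropped: dict[str, int] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def clip_and_buffer(raster: ReflectanceRaster, roi: QuadratROI) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixels whose centers lie inside the buffered ROI.

    Pixel membership is decided by the pixel *center* against the
    strictly-interior polygon test, so a boundary-grazing center is
    excluded — an unambiguous half-open convention.
    """
    poly = roi.buffered()
    xmin, ymin, xmax, ymax = poly.bounds
    bx0, by0, bx1, by1 = raster.bounds
    if xmax <= bx0 or xmin >= bx1 or ymax <= by0 or ymin >= by1:
        raise EmptyROIError(roi.id, "buffered polygon lies outside the raster extent")

    x0, y0 = raster.origin
    px = raster.pixel_size
    col_lo = max(0, int(np.floor((xmin - x0) / px)))
    col_hi = min(raster.shape[1], int(np.ceil((xmax - x0) / px)))
    row_lo = max(0, int(np.floor((y0 - ymax) / px)))
    row_hi = min(raster.shape[0], int(np.ceil((y0 - ymin) / px)))
    rows, cols = np.meshgrid(np.arange(row_lo, row_hi), np.arange(col_lo, col_hi), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    cx, cy = raster.pixel_centers(rows, cols)
    inside = shapely.contains_xy(poly, cx, cy)
    inside &= ~raster.nodata_mask[rows, cols]
    if not np.any(inside):
        raise EmptyROIError(roi.id, "no pixel centers fall inside the buffered polygon")
    return rows[inside], cols[inside]


def _band_values(raster: ReflectanceRaster, rows: np.ndarray, cols: np.ndarray) -> dict[str, np.ndarray]:
    return {b: raster.band(b)[rows, cols].astype(float) for b in BAND_NAMES}


def apply_mask_cascade(
    pixels: tuple[np.ndarray, np.ndarray],
    raster: ReflectanceRaster,
    roi_id: str = "<unnamed>",
) -> tuple[tuple[np.ndarray, np.ndarray], PixelMaskReport]:
    """Run the four-stage abnormal-pixel cascade on a pixel selection.

    Stages in order: (1) non-vegetation, NDVI < 0.20 from raw Red/NIR;
    (2) shadow, NIR < 0.05; (3) sensor saturation, any band > 0.95;
    (4) per-band percentile trim: within the stage-3 survivors each
    band flags values strictly below its 1st or strictly above its 99th
    percentile, and the valid set is the intersection of the per-band
    survivors.  Each stage tallies what it alone removed.
    """
    rows, cols = pixels
    if rows.size == 0:
        raise EmptyROIError(roi_id, "empty pixel selection")
    bands = _band_values(raster, rows, cols)
    n_total = rows.size

    nir, red = bands["NIR"], bands["Red"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(nir + red > 0, (nir - red) / (nir + red), -1.0)
    alive = ndvi >= NDVI_THRESHOLD
    n_nonveg = int(n_total - alive.sum())

    shadow = alive & (nir < NIR_SHADOW_THRESHOLD)
    n_shadow = int(shadow.sum())
    alive &= ~shadow

    any_saturated = np.zeros_like(alive)
    for b in BAND_NAMES:
        any_saturated |= bands[b] > SATURATION_THRESHOLD
    saturated = alive & any_saturated
    n_saturated = int(saturated.sum())
    alive &= ~saturated

    if not np.any(alive):
        raise EmptyROIError(roi_id, "all pixels removed by the masking cascade")

    n_quantile: dict[str, int] = {}
    survivors = alive.copy()
    for b in BAND_NAMES:
        vals = bands[b][alive]
        lo, hi = percentile(vals, [QUANTILE_LOW, QUANTILE_HIGH])
        flagged = alive & ((bands[b] < lo) | (bands[b] > hi))
        n_quantile[b] = int(flagged.sum())
        survivors &= ~flagged

    if not np.any(survivors):
        raise EmptyROIError(roi_id, "percentile trimming removed every surviving pixel")

    report = PixelMaskReport(
        n_total=n_total,
        n_nonveg=n_nonveg,
        n_shadow=n_shadow,
        n_saturated=n_saturated,
        n_quantile_excluded=n_quantile,
        n_valid=int(survivors.sum()),
    )
    return (rows[survivors], cols[survivors]), report


def band_statistics(
    pixels: tuple[np.ndarray, np.ndarray], raster: ReflectanceRaster
) -> dict[str, float]:
    """Per-band mean/median/std/min/max and 10th-90th percentiles.

    Keys are ``{band}_{stat}``; percentiles use the shared
    linear-interpolation convention and std is the sample (ddof=1)
    standard deviation.
    """
    rows, cols = pixels
    if rows.size < 2:
        raise DegenerateROIError(f"band statistics need >= 2 valid pixels; got {rows.size}")
    out: dict[str, float] = {}
    for b, vals in _band_values(raster, rows, cols).items():
        out[f"{b}_mean"] = float(np.mean(vals))
        out[f"{b}_median"] = float(np.median(vals))
        out[f"{b}_std"] = sample_std(vals)
        out[f"{b}_min"] = float(np.min(vals))
        out[f"{b}_max"] = float(np.max(vals))
        for q in range(10, 100, 10):
            out[f"{b}_p{q}"] = float(percentile(vals, q))
    return out


def raster_histogram_features(
    pixels: tuple[np.ndarray, np.ndarray], raster: ReflectanceRaster
) -> dict[str, float]:
    """Histogram-shape features per band (50 equal-width bins)."""
    rows, cols = pixels
    if rows.size < 2:
        raise DegenerateROIError(f"histogram features need >= 2 valid pixels; got {rows.size}")
    out: dict[str, float] = {}
    for b, vals in _band_values(raster, rows, cols).items():
        hf = histogram_features(vals)
        out[f"{b}_peak_location"] = hf.peak_location
        out[f"{b}_peak_frequency"] = hf.peak_frequency
        out[f"{b}_distribution_width"] = hf.distribution_width
    return out


def vegetation_indices(
    pixels: tuple[np.ndarray, np.ndarray],
    raster: ReflectanceRaster,
    savi_l: float = DEFAULT_SAVI_L,
) -> tuple[dict[str, float], dict[str, int]]:
    """Mean of each vegetation index over valid pixels.

    Per-pixel formulas::

        NDVI  = (NIR - Red) / (NIR + Red)
        NDRE  = (NIR - RedEdge) / (NIR + RedEdge)
        GNDVI = (NIR - Green) / (NIR + Green)
        MSR   = (NIR/Red - 1) / (NIR/Red + 1)
        EVI   = 2.5 (NIR - Red) / (NIR + 6 Red - 7.5 Blue + 1)
        SAVI  = 1.5 (NIR - Red) / (NIR + Red + L)

    Pixels with a non-positive denominator are dropped from that index's
    mean and tallied in the returned drop-count dict.
    """
    rows, cols = pixels
    if rows.size < 1:
        raise DegenerateROIError("vegetation indices need >= 1 valid pixel")
    b = _band_values(raster, rows, cols)
    nir, red, green, rededge, blue = b["NIR"], b["Red"], b["Green"], b["RedEdge"], b["Blue"]

    denominators = {
        "NDVI": nir + red,
        "NDRE": nir + rededge,
        "GNDVI": nir + green,
        "MSR": nir + red,  # equivalent to (NIR/Red + 1) > 0 for Red > 0
        "EVI": nir + 6.0 * red - 7.5 * blue + 1.0,
        "SAVI": nir + red + savi_l,
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        values = {
            "NDVI": (nir - red) / denominators["NDVI"],
            "NDRE": (nir - rededge) / denominators["NDRE"],
            "GNDVI": (nir - green) / denominators["GNDVI"],
            "MSR": (nir - red) / (nir + red),  # algebraic simplification of the ratio form
            "EVI": 2.5 * (nir - red) / denominators["EVI"],
            "SAVI": (1.0 + savi_l) * (nir - red) / denominators["SAVI"],
        }
    means: dict[str, float] = {}
    dropped: dict[str, int] = {}
    for name in VEGETATION_INDICES:
        ok = denominators[name] > 0
        dropped[name] = int(rows.size - ok.sum())
        if not np.any(ok):
            raise DegenerateROIError(f"index {name}: no pixel with positive denominator")
        means[f"{name}_mean"] = float(np.mean(values[name][ok]))
    return means, dropped


def extract_spectral_features(
    raster: ReflectanceRaster,
    roi: QuadratROI,
    savi_l: float = DEFAULT_SAVI_L,
) -> tuple[dict[str, float], PixelMaskReport]:
    """All spectral + geometric features for one ROI, with its mask report."""
    selection = clip_and_buffer(raster, roi)
    valid, report = apply_mask_cascade(selection, raster, roi_id=roi.id)
    features = band_statistics(valid, raster)
    features.update(raster_histogram_features(valid, raster))
    index_means, dropped = vegetation_indices(valid, raster, savi_l=savi_l)
    features.update(index_means)
    report.n_index_denominator_dropped = dropped
    features["roi_area_m2"] = float(roi.buffered().area)
    features["count_valid_pixels"] = float(report.n_valid)
    features["count_total_pixels"] = float(report.n_total)
    return features, report
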