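"""LiDAR point classification, normalization, and structural features.

Processing order per scene:

1. :func:`remove_outliers` — neighborhood-based statistical filtering
   (mean k-nearest-neighbor distance thresholded at global mean +
   ``sd_multiplier`` standard deviations).
2. :func:`classify_ground` — progressive morphological filtering on a
   gridded minimum surface with growing windows and slope-scaled
   elevation thresholds.
3. :func:`normalize_hag` — height above ground from a bilinear
   interpolation of the grid-minimum ground surface; non-ground points
   with HAG in [0.05, 3.0] m become vegetation.
4. :func:`structural_features` — the canopy structural catalog per
   buffered quadrat ROI: height statistics and percentiles, point
   densities, coverage above 0.3/1.0 m, vertical stratification
   proportions, echo-intensity statistics, and convex hull area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import ConvexHull, QhullError, cKDTree

from ._stats import histogram_features, percentile, sample_std
from .containers import (
    CLASS_GROUND,
    CLASS_NOISE,
    CLASS_UNASSIGNED,
    CLASS_VEGETATION,
    CanopyPointCloud,
    QuadratROI,
)

HAG_MIN = 0.05
HAG_MAX = 3.0

HEIGHT_PERCENTILES = (5, 10, 25, 50, 75, 90, 95)
#: Half-open [a, b) vertical strata with a closed top bin at the HAG cap.
HEIGHT_STRATA = ((0.0, 0.5), (0.5, 1.0), (1.0, 1.5), (1.5, HAG_MAX))
COVERAGE_THRESHOLDS = (0.3, 1.0)

STRUCTURAL_FEATURE_NAMES = (
    "Hmax",
    "Hmean",
    "Hstd",
    "Hcv",
    *[f"Hq{p:02d}" for p in HEIGHT_PERCENTILES],
    "HIQR",
    "density_total",
    "density_vegetation",
    "coverage_gt_0p3",
    "coverage_gt_1p0",
    *[f"strata_{a:g}_{b:g}" for a, b in HEIGHT_STRATA],
    "IntensityMean",
    "IntensityStd",
    "Intensity_peak_location",
    "Intensity_peak_frequency",
    "Intensity_distribution_width",
    "hull_area_m2",
)


@dataclass
class SparseROI:
    """Marker record for an ROI with too few vegetation points."""

    roi_id: str
    n_vegetation: int


def _min_surface(x: np.ndarray, y: np.ndarray, z: np.ndarray, cell_size: float):
    """Grid-minimum surface; empty cells filled from the nearest filled cell."""
    x0, y0 = x.min(), y.min()
    ncols = max(1, int(math.ceil((x.max() - x0) / cell_size)))
    nrows = max(1, int(math.ceil((y.max() - y0) / cell_size)))
    col = np.clip(((x - x0) / cell_size).astype(int), 0, ncols - 1)
    row = np.clip(((y - y0) / cell_size).astype(int), 0, nrows - 1)
    surf = np.full((nrows, ncols), np.inf)
    np.minimum.at(surf, (row, col), z)
    empty = ~np.isfinite(surf)
    if empty.all():
        raise ValueError("degenerate extent: no occupied grid cells")
    if empty.any():
        _, (ri, ci) = ndimage.distance_transform_edt(empty, return_indices=True)
        surf = surf[ri, ci]
    return surf, (row, col), (x0, y0, nrows, ncols)


def classify_ground(
    cloud: CanopyPointCloud,
    cell_size: float = 0.25,
    max_window: float = 2.0,
    slope_tolerance: float = 0.15,
    initial_threshold: float = 0.10,
    max_threshold: float = 2.0,
) -> CanopyPointCloud:
    """Progressive morphological ground filter.

    The minimum surface is opened with windows of growing size
    (3, 5, 9, ... cells up to ``max_window``); at each step, cells whose
    surface sits more than ``initial_threshold + slope_tolerance * w``
    (w = half window extent in metres, capped at ``max_threshold``)
    above the opened surface are replaced by it, progressively carving
    vegetation bumps out of the surface.  A point is labeled ground when
    its elevation is within ``initial_threshold`` of the final surface.
    Points already labeled noise are left untouched.
    """
    pts = cloud.points
    active = pts["cls"] != CLASS_NOISE
    if active.sum() < 3:
        raise ValueError("ground classification needs at least 3 non-noise points")
    x = pts.loc[active, "x"].to_numpy()
    y = pts.loc[active, "y"].to_numpy()
    z = pts.loc[active, "z"].to_numpy()
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("degenerate extent: all points coincident in xy")

    surf, (row, col), _ = _min_surface(x, y, z, cell_size)

    window_cells = 3
    while window_cells * cell_size <= max_window + 1e-9:
        opened = ndimage.grey_dilation(
            ndimage.grey_erosion(surf, size=(window_cells, window_cells)),
            size=(window_cells, window_cells),
        )
        half_extent = (window_cells // 2) * cell_size
        dh = min(initial_threshold + slope_tolerance * half_extent, max_threshold)
        bump = (surf - opened) > dh
        surf = np.where(bump, opened, surf)
        window_cells = 2 * window_cells - 1

    ground = (z - surf[row, col]) <= initial_threshold
    out = cloud.copy()
    cls = out.points["cls"].to_numpy()
    idx = np.flatnonzero(active.to_numpy())
    cls[idx[ground]] = CLASS_GROUND
    cls[idx[~ground]] = np.where(
        cls[idx[~ground]] == CLASS_GROUND, CLASS_UNASSIGNED, cls[idx[~ground]]
    )
    out.points["cls"] = cls
    return out


def remove_outliers(
    cloud: CanopyPointCloud, k_neighbors: int = 8, sd_multiplier: float = 3.0
) -> CanopyPointCloud:
    """Statistical outlier removal on mean k-nearest-neighbor distance.

    A point is labeled noise when its mean distance to its ``k_neighbors``
    nearest neighbors exceeds the global mean + ``sd_multiplier`` sample
    standard deviations of that quantity.  With too few points the cloud
    passes through unchanged (a warning is emitted).
    """
    pts = cloud.points
    n = len(pts)
    if n <= k_neighbors:
        warnings.warn(
            f"outlier removal skipped: {n} points <= k_neighbors={k_neighbors}", stacklevel=2
        )
        return cloud.copy()
    xyz = pts[["x", "y", "z"]].to_numpy()
    tree = cKDTree(xyz)
    dist, _ = tree.query(xyz, k=k_neighbors + 1)
    mean_dist = dist[:, 1:].mean(axis=1)  # exclude self (distance 0)
    threshold = mean_dist.mean() + sd_multiplier * np.std(mean_dist, ddof=1)
    out = cloud.copy()
    noisy = mean_dist > threshold
    cls = out.points["cls"].to_numpy()
    cls[noisy] = CLASS_NOISE
    out.points["cls"] = cls
    return out


def normalize_hag(cloud: CanopyPointCloud, cell_size: float = 0.25) -> CanopyPointCloud:
    """Height-above-ground normalization and vegetation labeling.

    The ground surface is the grid-minimum of classified ground points,
    bilinearly interpolated at each point's xy (nearest-edge beyond the
    grid).  Non-ground, non-noise points with HAG in [0.05, 3.0] m
    (closed bounds) are labeled vegetation; others revert to unassigned
    and are excluded from vegetation features.
    """
    pts = cloud.points
    ground = pts[pts["cls"] == CLASS_GROUND]
    if len(ground) == 0:
        raise ValueError("height normalization requires classified ground points")
    surf, _, (x0, y0, nrows, ncols) = _min_surface(
        ground["x"].to_numpy(), ground["y"].to_numpy(), ground["z"].to_numpy(), cell_size
    )
    row_centers = y0 + (np.arange(nrows) + 0.5) * cell_size
    col_centers = x0 + (np.arange(ncols) + 0.5) * cell_size
    interp = RegularGridInterpolator(
        (row_centers, col_centers), surf, method="linear", bounds_error=False, fill_value=None
    )
    qx = np.clip(pts["x"].to_numpy(), col_centers[0], col_centers[-1])
    qy = np.clip(pts["y"].to_numpy(), row_centers[0], row_centers[-1])
    hag = pts["z"].to_numpy() - interp(np.column_stack([qy, qx]))

    out = cloud.copy()
    out.points["hag"] = hag
    cls = out.points["cls"].to_numpy()
    candidate = (cls != CLASS_GROUND) & (cls != CLASS_NOISE)
    # closed bounds with float tolerance so points at exactly 0.05/3.0 m survive
    veg = candidate & (hag >= HAG_MIN - 1e-9) & (hag <= HAG_MAX + 1e-9)
    cls[candidate & ~veg] = CLASS_UNASSIGNED
    cls[veg] = CLASS_VEGETATION
    out.points["cls"] = cls
    return out


def _points_in_polygon(pts, polygon) -> np.ndarray:
    """Boolean membership mask with a bounding-box prefilter."""
    x = pts["x"].to_numpy()
    y = pts["y"].to_numpy()
    xmin, ymin, xmax, ymax = polygon.bounds
    candidate = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
    inside = np.zeros(len(pts), dtype=bool)
    if candidate.any():
        inside[candidate] = shapely.contains_xy(polygon, x[candidate], y[candidate])
    return inside


def structural_features(
    cloud: CanopyPointCloud,
    roi: QuadratROI,
    min_vegetation_points: int = 5,
) -> dict[str, float] | SparseROI:
    """Canopy structural feature catalog over one buffered ROI.

    Densities are counts over the buffered-ROI area; heights are HAG;
    strata proportions are over vegetation points and sum to 1; coverage
    uses strict ``>`` thresholds; the hull area is the 2D convex hull of
    the vegetation points.  Returns a :class:`SparseROI` marker instead
    of features when fewer than ``min_vegetation_points`` vegetation
    points fall inside the ROI.
    """
    if not cloud.has_hag:
        raise ValueError("structural features require a HAG-normalized cloud")
    poly = roi.buffered()
    area = poly.area
    pts = cloud.points
    inside = _points_in_polygon(pts, poly)
    roi_pts = pts[inside]
    veg = roi_pts[roi_pts["cls"] == CLASS_VEGETATION]
    if len(veg) < min_vegetation_points:
        return SparseROI(roi_id=roi.id, n_vegetation=len(veg))

    h = veg["hag"].to_numpy()
    intensity = veg["intensity"].to_numpy()
    out: dict[str, float] = {}
    out["Hmax"] = float(h.max())
    out["Hmean"] = float(h.mean())
    out["Hstd"] = sample_std(h)
    out["Hcv"] = out["Hstd"] / out["Hmean"] if out["Hmean"] > 0 else 0.0
    for p in HEIGHT_PERCENTILES:
        out[f"Hq{p:02d}"] = float(percentile(h, p))
    out["HIQR"] = out["Hq75"] - out["Hq25"]
    n_total = int((roi_pts["cls"] != CLASS_NOISE).sum())
    out["density_total"] = n_total / area
    out["density_vegetation"] = len(veg) / area
    out["coverage_gt_0p3"] = float(np.mean(h > COVERAGE_THRESHOLDS[0]))
    out["coverage_gt_1p0"] = float(np.mean(h > COVERAGE_THRESHOLDS[1]))
    for a, b in HEIGHT_STRATA:
        if b >= HAG_MAX:  # closed top bin
            frac = np.mean((h >= a) & (h <= b))
        else:
            frac = np.mean((h >= a) & (h < b))
        out[f"strata_{a:g}_{b:g}"] = float(frac)
    out["IntensityMean"] = float(intensity.mean())
    out["IntensityStd"] = sample_std(intensity)
    hf = histogram_features(intensity)
    out["Intensity_peak_location"] = hf.peak_location
    out["Intensity_peak_frequency"] = hf.peak_frequency
    out["Intensity_distribution_width"] = hf.distribution_width
    out["hull_area_m2"] = _hull_area(veg["x"].to_numpy(), veg["y"].to_numpy())
    return out


def _hull_area(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3:
        return 0.0
    try:
        hull = ConvexHull(np.column_stack([x, y]))
    except QhullError:  # collinear points span no area
        return 0.0
    return float(hull.volume)  # in 2D, "volume" is the polygon area


def process_cloud(
    cloud: CanopyPointCloud,
    k_neighbors: int = 8,
    sd_multiplier: float = 3.0,
    cell_size: float = 0.25,
    max_window: float = 2.0,
    slope_tolerance: float = 0.15,
) -> CanopyPointCloud:
    """Full classification chain: outliers -> ground -> HAG/vegetation."""
    cloud = remove_outliers(cloud, k_neighbors=k_neighbors, sd_multiplier=sd_multiplier)
    cloud = classify_ground(
        cloud, cell_size=cell_size, max_window=max_window, slope_tolerance=slope_tolerance
    )
    return normalize_hag(cloud, cell_size=cell_size)
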