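"""Core in-memory data containers shared across the pipeline.

The three carriers of field information are:

``ReflectanceRaster``
    A georeferenced 5-band reflectance grid (Blue, Green, Red, RedEdge,
    NIR), the spectral side of every quadrat.
``CanopyPointCloud``
    LiDAR returns with intensity and a ground/vegetation/noise class
    label, optionally height-above-ground normalized; the structural side.
``QuadratROI``
    A 1 m x 1 m sampling polygon with its measured biomass and batch
    metadata; the unit that links both modalities to ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

#: Canonical band order used everywhere (matches a 5-band multispectral camera).
BAND_NAMES = ("Blue", "Green", "Red", "RedEdge", "NIR")

# Point classes (values follow the LAS classification convention).
CLASS_UNASSIGNED = 0
CLASS_GROUND = 2
CLASS_VEGETATION = 3
CLASS_NOISE = 7

CLASS_LABELS = {
    CLASS_UNASSIGNED: "unassigned",
    CLASS_GROUND: "ground",
    CLASS_VEGETATION: "vegetation",
    CLASS_NOISE: "noise",
}


@dataclass
class ReflectanceRaster:
    """5-band reflectance grid with a simple north-up geotransform.

    ``data`` has shape (5, nrows, ncols) in :data:`BAND_NAMES` order.
    ``origin`` is the (x, y) map coordinate of the *top-left corner* of
    pixel (0, 0); x grows with columns, y decreases with rows.
    Reflectance is unitless, nominally in [0, 1].
    """

    data: np.ndarray
    origin: tuple[float, float]
    pixel_size: float
    nodata_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[0] != len(BAND_NAMES):
            raise ValueError(f"raster data must have shape (5, rows, cols); got {self.data.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.data.shape[1:], dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.data.shape[1:]:
                raise ValueError("nodata_mask shape must match band shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def band(self, name: str) -> np.ndarray:
        return self.data[BAND_NAMES.index(name)]

    def pixel_centers(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of the centers of the given pixels."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(cols) + 0.5) * self.pixel_size
        y = y0 - (np.asarray(rows) + 0.5) * self.pixel_size
        return x, y

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent."""
        x0, y0 = self.origin
        nrows, ncols = self.shape
        return (x0, y0 - nrows * self.pixel_size, x0 + ncols * self.pixel_size, y0)


@dataclass
class CanopyPointCloud:
    """LiDAR returns as a columnar table.

    ``points`` holds x, y, z (m), intensity (unitless DN) and ``cls``
    (see the CLASS_* constants).  ``hag`` (height above ground, m) is
    present only after normalization.
    """

    points: pd.DataFrame

    REQUIRED = ("x", "y", "z", "intensity", "cls")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.points.columns]
        if missing:
            raise ValueError(f"point cloud missing columns: {missing}")
        self.points = self.points.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_hag(self) -> bool:
        return "hag" in self.points.columns

    def subset(self, mask: np.ndarray) -> "CanopyPointCloud":
        return CanopyPointCloud(self.points.loc[np.asarray(mask)].reset_index(drop=True))

    def with_class(self, cls: int) -> pd.DataFrame:
        return self.points[self.points["cls"] == cls]

    def copy(self) -> "CanopyPointCloud":
        return CanopyPointCloud(self.points.copy())


@dataclass
class QuadratROI:
    """One ground-truth sampling quadrat.

    ``biomass`` is the oven-dry weight per unit area (kg m^-2) measured by
    clipping the quadrat; it is absent (None) for prediction-only ROIs.
    ``fertilizer_level`` is the fraction of the conventional fertilizer
    application rate for the plot the quadrat sits in.
    """

    id: str
    polygon: Polygon
    buffer_width: float = 0.075
    biomass: Optional[float] = None
    stage: str = "unknown"
    fertilizer_level: float = 1.0
    batch_date: str = ""

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError(f"ROI {self.id}: polygon must be simple, closed and non-empty")
        if not (0.0 <= self.buffer_width <= 0.5):
            raise ValueError(f"ROI {self.id}: buffer_width {self.buffer_width} out of range")

    def buffered(self) -> Polygon:
        """Inward-buffered polygon used for all feature extraction."""
        shrunk = self.polygon.buffer(-self.buffer_width)
        if shrunk.is_empty:
            raise ValueError(f"ROI {self.id}: inward buffer {self.buffer_width} m empties the polygon")
        return shrunk
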