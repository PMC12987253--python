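"""Readers and writers for the on-disk exchange formats.

Rasters travel as plain multi-band float32 TIFF plus a JSON sidecar
(`<name>.tif` + `<name>.json`) carrying the georeferencing (origin,
pixel size, band order, nodata value).  Point clouds travel as CSV with
columns x,y,z,intensity,cls[,hag].  Quadrat ROIs are GeoJSON
FeatureCollections; control points and ground truth are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, shape, mapping

from .containers import BAND_NAMES, CanopyPointCloud, QuadratROI, ReflectanceRaster

NODATA_VALUE = -9999.0


# ---------------------------------------------------------------- rasters

def write_raster(raster: ReflectanceRaster, path: str | Path) -> Path:
    path = Path(path)
    data = raster.data.copy()
    data[:, raster.nodata_mask] = NODATA_VALUE
    tifffile.imwrite(path, data)
    sidecar = {
        "origin": list(raster.origin),
        "pixel_size": raster.pixel_size,
        "band_order": list(BAND_NAMES),
        "nodata": NODATA_VALUE,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_raster(path: str | Path) -> ReflectanceRaster:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if list(sidecar["band_order"]) != list(BAND_NAMES):
        raise ValueError(
            f"unexpected band order {sidecar['band_order']}; expected {list(BAND_NAMES)}"
        )
    data = tifffile.imread(path).astype(np.float32)
    nodata = sidecar.get("nodata", NODATA_VALUE)
    mask = np.any(data == nodata, axis=0)
    data[:, mask] = 0.0
    return ReflectanceRaster(
        data=data,
        origin=tuple(sidecar["origin"]),
        pixel_size=float(sidecar["pixel_size"]),
        nodata_mask=mask,
    )


# ----------------------------------------------------------- point clouds

def write_point_cloud(cloud: CanopyPointCloud, path: str | Path) -> Path:
    path = Path(path)
    cloud.points.to_csv(path, index=False, float_format="%.6f")
    return path


def read_point_cloud(path: str | Path) -> CanopyPointCloud:
    df = pd.read_csv(path)
    return CanopyPointCloud(df)


# -------------------------------------------------------------------- ROIs

def write_rois(rois: Sequence[QuadratROI], path: str | Path) -> Path:
    features = []
    for roi in rois:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(roi.polygon),
                "properties": {
                    "id": roi.id,
                    "biomass_kg_m2": roi.biomass,
                    "stage": roi.stage,
                    "fertilizer_level": roi.fertilizer_level,
                    "batch_date": roi.batch_date,
                    "buffer_width": roi.buffer_width,
                },
            }
        )
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=2))
    return path


def read_rois(path: str | Path) -> list[QuadratROI]:
    collection = json.loads(Path(path).read_text())
    rois = []
    for feat in collection["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ValueError(f"ROI {props.get('id')}: geometry must be a Polygon")
        rois.append(
            QuadratROI(
                id=str(props["id"]),
                polygon=geom,
                buffer_width=float(props.get("buffer_width", 0.075)),
                biomass=props.get("biomass_kg_m2"),
                stage=props.get("stage", "unknown"),
                fertilizer_level=float(props.get("fertilizer_level", 1.0)),
                batch_date=props.get("batch_date", ""),
            )
        )
    return rois


# ---------------------------------------------------------- control points

def write_control_points(df: pd.DataFrame, path: str | Path) -> Path:
    cols = ["id", "src_x", "src_y", "ref_x", "ref_y"]
    df[cols].to_csv(path, index=False)
    return Path(path)


def read_control_points(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"id", "src_x", "src_y", "ref_x", "ref_y"} - set(df.columns)
    if missing:
        raise ValueError(f"control point file missing columns: {sorted(missing)}")
    return df
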