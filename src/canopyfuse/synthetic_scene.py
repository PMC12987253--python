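"""Synthetic co-registered field scenes with known ground-truth biomass.

Emulates one UAV flight batch over a fertilizer-gradient forage trial:
a 5-band reflectance orthomosaic, a LiDAR point cloud with intensity,
and a grid of 1 m x 1 m quadrats with known (generative) dry biomass.

The generative model is deliberately simple but reproduces the two
regime features that matter downstream:

* **Spectral saturation** — canopy cover c(b) = 1 - exp(-k b) saturates
  in biomass b, so NIR rises / Red falls quickly at low biomass and
  barely changes above ~2 kg m^-2, which drives the high-biomass
  underestimation the evaluation module must detect.
* **Structural saturation** — canopy height scale h(b) =
  h_max * b / (b + b_half) saturates with a different half-point, so
  LiDAR heights carry partially complementary information.

Vegetation point heights follow a right-skewed Beta(2, 3) profile
scaled by h(b); ground returns sit on a gently sloped terrain; shadow,
sensor-saturation and high-outlier contamination are injected at
configurable rates.  All sampling is driven by one seeded generator, so
identical (config, seed) pairs reproduce byte-identical scenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import box

from .containers import (
    CLASS_UNASSIGNED,
    BAND_NAMES,
    CanopyPointCloud,
    QuadratROI,
    ReflectanceRaster,
)
from . import io as cfio

#: Bare-soil and dense-canopy reflectance endpoints per band.  Pixel
#: reflectance is soil + (veg - soil) * cover, i.e. a linear mixture in
#: cover that saturates in biomass through c(b).  Soil NDVI is ~0.09 so
#: background pixels fall below the 0.20 vegetation-mask threshold.
SOIL_REFLECTANCE = {"Blue": 0.06, "Green": 0.08, "Red": 0.10, "RedEdge": 0.13, "NIR": 0.12}
CANOPY_REFLECTANCE = {"Blue": 0.03, "Green": 0.07, "Red": 0.03, "RedEdge": 0.28, "NIR": 0.55}

#: Vegetation point heights are clipped to this window (m); the same
#: window is the downstream height-above-ground retention filter.
HEIGHT_MIN = 0.05
HEIGHT_MAX = 3.0

FERTILIZER_LEVELS = (0.0, 0.5, 0.75, 1.0, 1.25, 1.5)


@dataclass(frozen=True)
class SceneConfig:
    """Generative parameters for one synthetic flight batch.

    Defaults encode the acquisition regime being emulated: 1 m quadrats,
    2 cm-class ground sampling distance rounded to a 0.05 m grid,
    150-200 pts m^-2 LiDAR density, per-quadrat dry biomass drawn from a
    truncated normal (mean 1.27, sd 0.41 kg m^-2) on 0.3-2.2 kg m^-2,
    and low single-digit-percent pixel contamination.
    """

    n_quadrats: int = 60
    quadrat_side: float = 1.0
    pixel_size: float = 0.05
    biomass_range: tuple[float, float] = (0.3, 2.2)
    biomass_distribution: str = "truncnorm"  # or "uniform" (spans the range evenly)
    biomass_mean: float = 1.27
    biomass_sd: float = 0.41
    noise_sd_reflectance: float = 0.015
    noise_sd_height: float = 0.02
    shadow_fraction: float = 0.03
    saturation_fraction: float = 0.01
    outlier_count_per_quadrat: int = 2
    points_per_m2: float = 175.0
    stage_label: str = "branching"
    fertilizer_levels: tuple[float, ...] = FERTILIZER_LEVELS
    fertilizer_effect: float = 0.12  # kg m^-2 shift per unit fertilizer level
    cover_rate_k: float = -math.log(0.05) / 2.0  # c(2.0) ~= 0.95
    height_max: float = 1.2
    height_half_saturation: float = 0.7
    canopy_interception: float = 0.85  # fraction of pulses stopped by a full canopy
    #: Per-quadrat lognormal scatter decoupling each modality's latent
    #: drive from dry biomass: two quadrats of equal dry weight differ in
    #: canopy architecture, water status and greenness, so neither the
    #: spectral nor the structural signal determines biomass exactly.
    #: Structure is the more indirect proxy (height says little about
    #: tissue density), hence the larger structural scatter.
    cover_scatter_sd: float = 0.10
    height_scatter_sd: float = 0.20
    terrain_slope: float = 0.02  # m per m along x
    cloud_shift: tuple[float, float] = (0.0, 0.0)
    batch_date: str = "2025-08-13"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shadow_fraction", "saturation_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        lo, hi = self.biomass_range
        if not (0.0 < lo < hi <= 3.0):
            raise ValueError(f"biomass_range must lie within (0, 3]; got {self.biomass_range}")
        if self.points_per_m2 <= 0:
            raise ValueError("points_per_m2 must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_quadrats < 1:
            raise ValueError("n_quadrats must be >= 1")
        for lvl in self.fertilizer_levels:
            if lvl not in FERTILIZER_LEVELS:
                raise ValueError(f"fertilizer level {lvl} not in {FERTILIZER_LEVELS}")

    def cover_fraction(self, biomass: np.ndarray) -> np.ndarray:
        """Canopy cover c(b) = 1 - exp(-k b): monotone, saturating."""
        return 1.0 - np.exp(-self.cover_rate_k * np.asarray(biomass))

    def height_scale(self, biomass: np.ndarray) -> np.ndarray:
        """Canopy height scale h(b) = h_max * b / (b + b_half)."""
        b = np.asarray(biomass)
        return self.height_max * b / (b + self.height_half_saturation)


@dataclass
class SyntheticScene:
    """One generated flight batch and its generative bookkeeping."""

    raster: ReflectanceRaster
    cloud: CanopyPointCloud
    quadrats: list[QuadratROI]
    true_params: pd.DataFrame  # per-quadrat: biomass, cover, height_scale, ...
    control_points: pd.DataFrame
    config: SceneConfig


def _quadrat_grid(config: SceneConfig) -> tuple[list[tuple[float, float]], float, float]:
    """Lower-left corners of the quadrats on a regular grid.

    Quadrats are spaced one quadrat-side apart (pitch = 2 sides) with a
    one-side margin to the scene edge, mirroring edge avoidance in field
    layouts.
    """
    side = config.quadrat_side
    ncols = math.ceil(math.sqrt(config.n_quadrats))
    nrows = math.ceil(config.n_quadrats / ncols)
    pitch = 2.0 * side
    width = 2 * side + ncols * pitch - side
    height = 2 * side + nrows * pitch - side
    corners = []
    for i in range(config.n_quadrats):
        r, c = divmod(i, ncols)
        corners.append((side + c * pitch, side + r * pitch))
    return corners, width, height


def reflectance_response(config: SceneConfig, cover: np.ndarray) -> dict[str, np.ndarray]:
    """Deterministic mean reflectance per band for a given cover fraction."""
    cover = np.asarray(cover, dtype=float)
    return {
        b: SOIL_REFLECTANCE[b] + (CANOPY_REFLECTANCE[b] - SOIL_REFLECTANCE[b]) * cover
        for b in BAND_NAMES
    }


def _draw_biomass(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.biomass_range
    if config.biomass_distribution == "uniform":
        return rng.uniform(lo, hi, size=config.n_quadrats)
    if config.biomass_distribution != "truncnorm":
        raise ValueError(f"unknown biomass_distribution {config.biomass_distribution!r}")
    a = (lo - config.biomass_mean) / config.biomass_sd
    b = (hi - config.biomass_mean) / config.biomass_sd
    dist = stats.truncnorm(a, b, loc=config.biomass_mean, scale=config.biomass_sd)
    return dist.rvs(size=config.n_quadrats, random_state=rng)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate a fully co-registered synthetic scene.

    The raster and the quadrat polygons live in the reference frame; the
    point cloud is rigidly shifted by ``config.cloud_shift`` (zero by
    default) to let the registration stage be exercised, and seven
    control-point pairs tying the cloud frame back to the reference
    frame are emitted alongside.
    """
    rng = np.random.default_rng(config.seed)
    corners, width, height = _quadrat_grid(config)
    side = config.quadrat_side
    px = config.pixel_size

    ncols_px = int(round(width / px))
    nrows_px = int(round(height / px))
    if ncols_px < 1 or nrows_px < 1:
        raise ValueError("quadrat grid does not fit the raster extent")
    origin = (0.0, height)  # top-left corner; y decreases with rows

    # ---- per-quadrat latent state -------------------------------------
    fert = np.array(
        [config.fertilizer_levels[i % len(config.fertilizer_levels)] for i in range(config.n_quadrats)]
    )
    biomass = _draw_biomass(config, rng)
    biomass = biomass + config.fertilizer_effect * (fert - float(np.mean(config.fertilizer_levels)))
    biomass = np.clip(biomass, *config.biomass_range)
    # each modality sees biomass through its own noisy latent drive
    b_spectral = biomass * np.exp(rng.normal(0.0, config.cover_scatter_sd, config.n_quadrats))
    b_structural = biomass * np.exp(rng.normal(0.0, config.height_scatter_sd, config.n_quadrats))
    cover = config.cover_fraction(b_spectral)
    hscale = config.height_scale(b_structural)
    cover_struct = config.cover_fraction(b_structural)  # drives LiDAR returns/intensity

    # ---- raster -------------------------------------------------------
    cover_map = np.zeros((nrows_px, ncols_px), dtype=float)  # background = bare soil
    quadrat_pixel_masks = []
    for (qx, qy), c in zip(corners, cover):
        col0 = int(round(qx / px))
        col1 = int(round((qx + side) / px))
        row0 = int(round((height - (qy + side)) / px))
        row1 = int(round((height - qy) / px))
        cover_map[row0:row1, col0:col1] = c
        quadrat_pixel_masks.append((slice(row0, row1), slice(col0, col1)))

    means = reflectance_response(config, cover_map)
    data = np.empty((len(BAND_NAMES), nrows_px, ncols_px), dtype=np.float32)
    for bi, band in enumerate(BAND_NAMES):
        noise = (
            rng.normal(0.0, config.noise_sd_reflectance, size=cover_map.shape)
            if config.noise_sd_reflectance > 0
            else 0.0
        )
        data[bi] = np.clip(means[band] + noise, 0.0, 1.2)

    # contamination inside quadrats: shadow scales all bands so NIR < 0.05
    # (NDVI unchanged -> caught by the NIR stage); saturation forces NIR > 0.95.
    nir_idx = BAND_NAMES.index("NIR")
    for sl in quadrat_pixel_masks:
        block = data[:, sl[0], sl[1]]
        n_px = block.shape[1] * block.shape[2]
        if config.shadow_fraction > 0:
            shadow = rng.random(n_px).reshape(block.shape[1:]) < config.shadow_fraction
            factor = np.where(shadow, 0.04 / np.maximum(block[nir_idx], 1e-6), 1.0)
            block *= factor[None, :, :]
        if config.saturation_fraction > 0:
            saturated = rng.random(n_px).reshape(block.shape[1:]) < config.saturation_fraction
            block[nir_idx][saturated] = 0.97
        data[:, sl[0], sl[1]] = block

    raster = ReflectanceRaster(data=data, origin=origin, pixel_size=px)

    # ---- point cloud --------------------------------------------------
    def terrain(x, y):
        return config.terrain_slope * np.asarray(x)

    frames = []
    # background ground returns over the whole extent
    n_bg = rng.poisson(config.points_per_m2 * width * height * 0.35)
    bx = rng.uniform(0.0, width, n_bg)
    by = rng.uniform(0.0, height, n_bg)
    frames.append(
        pd.DataFrame(
            {
                "x": bx,
                "y": by,
                "z": terrain(bx, by) + rng.normal(0.0, 0.01, n_bg),
                "intensity": np.clip(rng.normal(60.0, 10.0, n_bg), 0, None),
            }
        )
    )

    for qi, ((qx, qy), b, c, h) in enumerate(zip(corners, biomass, cover_struct, hscale)):
        area = side * side
        n_total = rng.poisson(config.points_per_m2 * area)
        # a fraction of pulses reaches the ground even under a closed
        # canopy (multi-return penetration), keeping the ground model fed
        n_veg = rng.binomial(n_total, config.canopy_interception * c)
        n_gnd = n_total - n_veg
        # vegetation returns: right-skewed Beta(2,3) height profile
        vx = rng.uniform(qx, qx + side, n_veg)
        vy = rng.uniform(qy, qy + side, n_veg)
        vh = np.clip(rng.beta(2.0, 3.0, n_veg) * h, HEIGHT_MIN, HEIGHT_MAX)
        vz = terrain(vx, vy) + vh
        if config.noise_sd_height > 0:
            vz = vz + rng.normal(0.0, config.noise_sd_height, n_veg)
        vint = np.clip(rng.normal(120.0 + 80.0 * c, 15.0, n_veg), 0, None)
        # ground returns that penetrated the canopy
        gx = rng.uniform(qx, qx + side, n_gnd)
        gy = rng.uniform(qy, qy + side, n_gnd)
        gz = terrain(gx, gy) + rng.normal(0.0, 0.01, n_gnd)
        gint = np.clip(rng.normal(60.0, 10.0, n_gnd), 0, None)
        # high outliers well above the canopy (birds, air returns)
        n_out = config.outlier_count_per_quadrat
        ox = rng.uniform(qx, qx + side, n_out)
        oy = rng.uniform(qy, qy + side, n_out)
        oz = terrain(ox, oy) + rng.uniform(4.0, 9.0, n_out)
        oint = np.clip(rng.normal(40.0, 10.0, n_out), 0, None)
        frames.append(
            pd.DataFrame(
                {
                    "x": np.concatenate([vx, gx, ox]),
                    "y": np.concatenate([vy, gy, oy]),
                    "z": np.concatenate([vz, gz, oz]),
                    "intensity": np.concatenate([vint, gint, oint]),
                }
            )
        )

    pts = pd.concat(frames, ignore_index=True)
    pts["cls"] = CLASS_UNASSIGNED
    dx, dy = config.cloud_shift
    pts["x"] += dx
    pts["y"] += dy
    cloud = CanopyPointCloud(pts)

    # ---- control points (reference frame <- cloud frame) --------------
    ref = np.array(
        [
            (0.5, 0.5),
            (width - 0.5, 0.5),
            (0.5, height - 0.5),
            (width - 0.5, height - 0.5),
            (width / 2, height / 2),
            (width / 2, 0.5),
            (0.5, height / 2),
        ]
    )
    control_points = pd.DataFrame(
        {
            "id": [f"cp{i + 1}" for i in range(len(ref))],
            "src_x": ref[:, 0] + dx,
            "src_y": ref[:, 1] + dy,
            "ref_x": ref[:, 0],
            "ref_y": ref[:, 1],
        }
    )

    # ---- quadrat ROIs and bookkeeping ---------------------------------
    quadrats = []
    for qi, ((qx, qy), b, f) in enumerate(zip(corners, biomass, fert)):
        quadrats.append(
            QuadratROI(
                id=f"plot_{config.batch_date}_{qi:03d}",
                polygon=box(qx, qy, qx + side, qy + side),
                biomass=float(b),
                stage=config.stage_label,
                fertilizer_level=float(f),
                batch_date=config.batch_date,
            )
        )
    true_params = pd.DataFrame(
        {
            "id": [q.id for q in quadrats],
            "biomass": biomass,
            "cover_fraction": cover,
            "cover_fraction_structural": cover_struct,
            "height_scale": hscale,
            "fertilizer_level": fert,
            "stage": config.stage_label,
        }
    )
    return SyntheticScene(
        raster=raster,
        cloud=cloud,
        quadrats=quadrats,
        true_params=true_params,
        control_points=control_points,
        config=config,
    )


def write_scene(scene: SyntheticScene, outdir: str | Path) -> dict[str, Path]:
    """Persist a scene: TIFF+JSON raster, CSV cloud, GeoJSON ROIs, CSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "raster": cfio.write_raster(scene.raster, outdir / "reflectance.tif"),
        "cloud": cfio.write_point_cloud(scene.cloud, outdir / "point_cloud.csv"),
        "rois": cfio.write_rois(scene.quadrats, outdir / "quadrats.geojson"),
        "control_points": cfio.write_control_points(
            scene.control_points, outdir / "control_points.csv"
        ),
    }
    gt = scene.true_params[["id", "biomass", "fertilizer_level", "stage"]]
    gt = gt.rename(columns={"biomass": "biomass_kg_m2"})
    gt_path = outdir / "ground_truth.csv"
    gt.to_csv(gt_path, index=False)
    paths["ground_truth"] = gt_path
    return paths
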