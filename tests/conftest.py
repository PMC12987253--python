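"""Shared fixtures: small synthetic scenes and fast model configurations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from canopyfuse import SceneConfig, generate_scene
from canopyfuse.containers import BAND_NAMES, CanopyPointCloud, ReflectanceRaster
from canopyfuse.pointcloud_features import process_cloud

#: Small tree budgets keep unit-test model fits fast without changing behaviour.
FAST_HYPERPARAMETERS = {
    "RF": {"n_estimators": 40},
    "ET": {"n_estimators": 40},
    "HGB": {"max_iter": 60},
}


@pytest.fixture(scope="session")
def small_scene():
    """30-quadrat default-noise scene shared by read-only tests."""
    return generate_scene(SceneConfig(n_quadrats=30, seed=11))


@pytest.fixture(scope="session")
def processed_small_cloud(small_scene):
    return process_cloud(small_scene.cloud)


@pytest.fixture(scope="session")
def spanning_scene():
    """200 quadrats spanning the biomass range uniformly (for rank checks)."""
    return generate_scene(
        SceneConfig(n_quadrats=200, seed=5, biomass_distribution="uniform")
    )


def make_uniform_raster(values: dict[str, float], shape=(20, 20), pixel_size=0.05):
    """Constant-valued raster (one reflectance per band) for hand-built cases."""
    data = np.stack(
        [np.full(shape, values[b], dtype=np.float32) for b in BAND_NAMES]
    )
    return ReflectanceRaster(data=data, origin=(0.0, shape[0] * pixel_size), pixel_size=pixel_size)


def make_cloud(x, y, z, intensity=None, cls=0):
    n = len(x)
    return CanopyPointCloud(
        pd.DataFrame(
            {
                "x": np.asarray(x, float),
                "y": np.asarray(y, float),
                "z": np.asarray(z, float),
                "intensity": np.full(n, 100.0) if intensity is None else np.asarray(intensity, float),
                "cls": np.full(n, cls, dtype=int),
            }
        )
    )
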