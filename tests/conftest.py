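import numpy as np
import pytest

import phenocloud as pc
from phenocloud.core import build_knn
from phenocloud.geometry import estimate_field


@pytest.fixture(scope="session")
def plant_clean():
    """Default 3-leaf plant, no noise or outliers."""
    return pc.generate_plant(
        pc.PlantSpec(seed=11, noise_sd=0.0, outlier_fraction=0.0))


@pytest.fixture(scope="session")
def plant_noisy():
    """Default 3-leaf plant with 0.3 mm noise, no outliers."""
    return pc.generate_plant(
        pc.PlantSpec(seed=11, noise_sd=0.3, outlier_fraction=0.0))


@pytest.fixture(scope="session")
def plant_field(plant_noisy):
    """Noisy plant plus its k-NN graph and curvature field (k=15)."""
    cloud, truth = plant_noisy
    graph = build_knn(cloud, 15)
    field = estimate_field(cloud, graph)
    return cloud, truth, graph, field


@pytest.fixture(scope="session")
def benchmark6():
    """Six benchmark plants spanning 3..8 leaves, 0.3 mm noise."""
    return pc.make_benchmark_suite(list(range(6)))


def sample_sphere(n, radius, center=(0.0, 0.0, 0.0), seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = np.asarray(center) + radius * v
    if noise:
        pts = pts + rng.normal(0.0, noise, pts.shape)
    return pts


def sample_cylinder(n, radius, length, seed=0, noise=0.0, half=False,
                    axis="y"):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, length, n)
    phi = rng.uniform(0.0, np.pi if half else 2 * np.pi, n)
    pts = np.column_stack(
        [radius * np.cos(phi), t, radius * np.sin(phi)])
    if noise:
        pts = pts + rng.normal(0.0, noise, pts.shape)
    order = {"x": [1, 0, 2], "y": [0, 1, 2], "z": [0, 2, 1]}[axis]
    return pts[:, order]
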