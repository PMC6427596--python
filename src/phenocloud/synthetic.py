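"""Seedable maize-like point clouds with analytically known traits.

The model is deliberately simple — a vertical stem cylinder plus ruled leaf
blades on constant-curvature midribs — but it reproduces the statistical
structure the pipeline assumes: smooth low-curvature surfaces, high
curvature along leaf edges and tips, optional one-sided (half-azimuth) stem
coverage as a hand-held scanner would see, isotropic Gaussian surface
noise, and a sparse fraction of bounding-box outliers.

Blades diverge from the stem one internode above their node, the way a
maize sheath wraps the stem before the ligule, so the stem-diameter window
(the third internode) contains only stem points.

Coordinates are millimetres, vertical axis +y, stem base at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PointCloud
from .errors import ParameterError
from .traits import canopy_breadth

__all__ = ["PlantSpec", "GroundTruth", "generate_plant",
           "make_benchmark_suite"]


@dataclass
class PlantSpec:
    """Parameters of one synthetic plant; all lengths in mm."""

    n_leaves: int = 3
    stem_height: float = 400.0
    stem_radius: float = 7.0
    internode_lengths: list | None = None
    leaf_length: float | list = 300.0
    leaf_width: float | list = 40.0
    leaf_arc: float | list = 1.2       # midrib bend (rad over the blade)
    leaf_tilt: float | list = 0.6      # divergence from vertical (rad)
    phyllotaxy: list | None = None     # per-leaf azimuth (deg); None = drawn
    surface_spacing: float = 1.8
    noise_sd: float = 0.3
    outlier_fraction: float = 0.005
    stem_half_azimuth: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3 <= self.n_leaves <= 8:
            raise ParameterError("n_leaves must be in [3, 8]")
        if min(self.stem_height, self.stem_radius,
               self.surface_spacing) <= 0:
            raise ParameterError("stem dimensions and spacing must be > 0")
        if not 0 <= self.outlier_fraction <= 0.05:
            raise ParameterError("outlier_fraction must be in [0, 0.05]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.internode_lengths is None:
            self.internode_lengths = _default_internodes(
                self.n_leaves, self.stem_height)
        self.internode_lengths = [float(v) for v in self.internode_lengths]
        if len(self.internode_lengths) < 3:
            raise ParameterError("need >= 3 internodes for a third internode")
        if any(v <= 0 for v in self.internode_lengths):
            raise ParameterError("internode lengths must be > 0")
        if sum(self.internode_lengths) > self.stem_height + 1e-9:
            raise ParameterError(
                "internode lengths must sum to <= stem_height")
        for name in ("leaf_length", "leaf_width", "leaf_arc", "leaf_tilt"):
            val = getattr(self, name)
            if np.isscalar(val):
                val = [float(val)] * self.n_leaves
            val = [float(v) for v in val]
            if len(val) != self.n_leaves:
                raise ParameterError(f"{name} must have one value per leaf")
            if any(v <= 0 for v in val):
                raise ParameterError(f"{name} values must be > 0")
            setattr(self, name, val)
        if self.phyllotaxy is not None:
            self.phyllotaxy = [float(v) for v in self.phyllotaxy]
            if len(self.phyllotaxy) != self.n_leaves:
                raise ParameterError("phyllotaxy needs one azimuth per leaf")


def _default_internodes(n_leaves: int, stem_height: float) -> list:
    # internodes elongate acropetally; they occupy 55% of the stem
    w = 1.3 ** np.arange(n_leaves)
    return list(0.55 * stem_height * w / w.sum())


@dataclass
class GroundTruth:
    plant_height: float
    stem_diameter: float
    canopy_breadth: float
    third_internode_window: tuple
    labels: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "plant_height_mm": self.plant_height,
            "stem_diameter_mm": self.stem_diameter,
            "canopy_breadth_mm": self.canopy_breadth,
            "third_internode_window_mm": list(self.third_internode_window),
        }


def _sample_stem(spec: PlantSpec) -> np.ndarray:
    d = spec.surface_spacing
    arc = (np.pi if spec.stem_half_azimuth else 2 * np.pi) * spec.stem_radius
    n_y = max(2, int(np.ceil(spec.stem_height / d)) + 1)
    n_phi = max(3, int(np.ceil(arc / d)) + 1)
    y = np.linspace(0.0, spec.stem_height, n_y)
    if spec.stem_half_azimuth:
        phi = np.linspace(0.0, np.pi, n_phi)
    else:
        phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    yy, pp = np.meshgrid(y, phi, indexing="ij")
    r = spec.stem_radius
    return np.column_stack([
        (r * np.cos(pp)).ravel(), yy.ravel(), (r * np.sin(pp)).ravel()])


def _midrib(t: np.ndarray, length: float, tilt: float, arc: float
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Constant-curvature midrib in the (radial, vertical) plane.

    Returns radial offset rho(t), height gain h(t) and tangent angle
    theta(t) from vertical; arc length is exactly ``length``.
    """
    theta = tilt + arc * t
    rho = length * (np.cos(tilt) - np.cos(theta)) / arc
    h = length * (np.sin(theta) - np.sin(tilt)) / arc
    return rho, h, theta


def _emergence_height(spec: PlantSpec, j: int, nodes: np.ndarray) -> float:
    """Height at which blade j diverges from the stem.

    Blades are spread over the lower three quarters of the stem, but a
    blade rising through the third internode would hug the stem inside the
    stem-diameter window, so emergences that could not clear the radial
    gate by the window bottom are pushed above the window top — mimicking
    the sheath wrapping the stem past the measured internode.
    """
    h = spec.stem_height
    proposed = (j + 1) / (spec.n_leaves + 1) * 0.75 * h
    win_low, win_high = float(nodes[2]), float(nodes[3])
    # radial clearance 2 r at the window bottom, divergence angle >= tilt
    clearance = 2.0 * spec.stem_radius / np.tan(spec.leaf_tilt[j])
    if win_low - clearance < proposed < win_high:
        proposed = win_high + 2.0 * (j + 1)
    return float(min(proposed, 0.9 * h))


def _sample_leaf(spec: PlantSpec, j: int, azimuth_deg: float,
                 emergence: float) -> np.ndarray:
    d = spec.surface_spacing
    length = spec.leaf_length[j]
    width = spec.leaf_width[j]
    az = np.deg2rad(azimuth_deg)
    u = np.array([np.cos(az), 0.0, np.sin(az)])      # outward direction
    w_dir = np.array([-np.sin(az), 0.0, np.cos(az)])  # across the blade
    base = spec.stem_radius * u + np.array([0.0, emergence, 0.0])

    n_t = max(2, int(np.ceil(length / d)) + 1)
    t = np.linspace(0.0, 1.0, n_t)
    rho, h, _ = _midrib(t, length, spec.leaf_tilt[j], spec.leaf_arc[j])
    spine = base[None, :] + rho[:, None] * u[None, :]
    spine[:, 1] += h
    half_w = 0.5 * width * np.sqrt(np.clip(1.0 - (2 * t - 1) ** 2, 0.0, 1.0))

    rows = []
    for i in range(n_t):
        n_s = max(1, int(np.ceil(2 * half_w[i] / d)) + 1)
        s = (np.linspace(-half_w[i], half_w[i], n_s)
             if n_s > 1 else np.zeros(1))
        rows.append(spine[i][None, :] + s[:, None] * w_dir[None, :])
    return np.vstack(rows)


def generate_plant(spec: PlantSpec) -> tuple[PointCloud, GroundTruth]:
    """Sample one plant; deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    nodes = np.concatenate([[0.0], np.cumsum(spec.internode_lengths)])

    if spec.phyllotaxy is None:
        azimuths = [(j % 2) * 180.0 + float(rng.uniform(-12.0, 12.0))
                    for j in range(spec.n_leaves)]
    else:
        azimuths = spec.phyllotaxy

    parts = [_sample_stem(spec)]
    labels = [np.full(len(parts[0]), "stem", dtype=object)]
    for j in range(spec.n_leaves):
        emergence = _emergence_height(spec, j, nodes)
        leaf = _sample_leaf(spec, j, azimuths[j], emergence)
        parts.append(leaf)
        labels.append(np.full(len(leaf), f"leaf_{j}", dtype=object))

    clean = np.vstack(parts)
    label = np.concatenate(labels)
    n = len(clean)

    # ground-truth traits from the noise-free geometry
    inset = 0.05 * spec.internode_lengths[2]
    window = (float(nodes[2] + inset), float(nodes[3] - inset))
    clean_cloud = PointCloud(clean.copy())
    breadth_true, _ = canopy_breadth(clean_cloud)
    truth = GroundTruth(
        plant_height=spec.stem_height,
        stem_diameter=2.0 * spec.stem_radius,
        canopy_breadth=breadth_true,
        third_internode_window=window,
        labels=label,
    )

    pts = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    n_out = int(round(spec.outlier_fraction * n))
    if n_out:
        lo, hi = clean.min(axis=0), clean.max(axis=0)
        center, half = (lo + hi) / 2, (hi - lo) / 2
        lo_i, hi_i = center - 1.5 * half, center + 1.5 * half
        which = rng.choice(n, size=n_out, replace=False)
        pts[which] = rng.uniform(lo_i, hi_i, size=(n_out, 3))
        label[which] = "outlier"
    truth.labels = label
    return PointCloud(pts), truth


def make_benchmark_suite(seeds: list, noise_sd: float = 0.3,
                         outlier_fraction: float = 0.0
                         ) -> list[tuple[PointCloud, GroundTruth]]:
    """One plant per seed, cycling leaf counts 3..8 with seeded sizes.

    Heights span 250-900 mm and stem radii 4-12 mm, emulating growth from
    the trefoil to the jointing stage.
    """
    if not len(seeds):
        raise ParameterError("seeds must be non-empty")
    out = []
    for pos, seed in enumerate(seeds):
        n_leaves = 3 + pos % 6
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        height = float(rng.uniform(250.0, 900.0))
        radius = float(rng.uniform(4.0, 12.0))
        length = float(rng.uniform(0.45, 0.6)) * height
        spec = PlantSpec(
            n_leaves=n_leaves,
            stem_height=height,
            stem_radius=radius,
            leaf_length=length,
            leaf_width=0.13 * length,
            noise_sd=noise_sd,
            outlier_fraction=outlier_fraction,
            seed=int(seed) & 0x7FFFFFFF,
        )
        out.append(generate_plant(spec))
    return out
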