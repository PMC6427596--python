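"""Region-aware bilateral denoising and a Laplacian baseline.

Points are split by surface variation into a "single" (flat, low-curvature)
region that is left untouched and a "rich" (feature-carrying) region that is
smoothed with a point-cloud bilateral filter: each rich point moves along
its own normal by a displacement

    alpha = sum_i w1(x_i) w2(y_i) y_i / sum_i w1(x_i) w2(y_i)

where x_i = ||p - p_i|| is the spatial offset to neighbor i,
y_i = <p_i - p, n> is that neighbor's height above the local tangent plane,
w1/w2 are Gaussian kernels with per-point scales sigma1 (max neighbor
distance) and sigma2 (standard deviation of the projections y_i). The range
kernel w2 shuts the filter off across sharp features, which is what
preserves leaf edges.

The Laplacian baseline is the classical umbrella operator
p' = p + lambda * (mean(neighborhood) - p), with the self-inclusive
neighborhood average, applied to every point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NeighborhoodGraph, PointCloud, build_knn
from .errors import ParameterError
from .geometry import estimate_field

__all__ = [
    "RegionLabels", "BilateralParams", "DenoiseReport", "region_division",
    "bilateral_filter", "laplace_filter", "displacement_metrics",
    "error_reduction_percent",
]

#: Lower bound on sigma2 so the range kernel stays defined when every
#: neighbor projection coincides (exact plane).
SIGMA2_FLOOR_MM = 1e-6


@dataclass
class RegionLabels:
    """Boolean mask: True where a point is feature-rich."""

    rich: np.ndarray
    threshold: float

    @property
    def single(self) -> np.ndarray:
        return ~self.rich


@dataclass
class BilateralParams:
    k: int = 15
    iterations: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")


@dataclass
class DenoiseReport:
    max_error: float
    avg_error: float
    n_moved: int


def region_division(field) -> RegionLabels:
    """Mark each point single (sigma below the cloud mean) or rich."""
    sigma = np.asarray(field.curvature, dtype=np.float64)
    threshold = float(sigma.mean())
    return RegionLabels(rich=~(sigma < threshold), threshold=threshold)


def _bilateral_pass(points: np.ndarray, normals: np.ndarray,
                    rich: np.ndarray, graph: NeighborhoodGraph
                    ) -> tuple[np.ndarray, int]:
    """One Jacobi-style bilateral sweep; returns new points and the count
    of rich points whose kernel weights all vanished (left unmoved)."""
    k = graph.k
    nbr = points[graph.indices]                       # (n, k, 3)
    diff = nbr - points[:, None, :]
    x = np.linalg.norm(diff, axis=2)                  # (n, k)
    y = np.einsum("nkj,nj->nk", diff, normals)        # projections on n

    sigma1 = x.max(axis=1)
    sigma1 = np.where(sigma1 > 0, sigma1, 1.0)        # coincident cloud
    if k > 1:
        sigma2 = y.std(axis=1, ddof=1)
    else:
        sigma2 = np.zeros(len(points))
    sigma2 = np.maximum(sigma2, SIGMA2_FLOOR_MM)

    # log-domain weights, normalized per point so the largest weight is 1:
    # the ratio defining alpha is unchanged and cannot underflow to 0/0
    log_w = (-x ** 2 / (2.0 * sigma1[:, None] ** 2)
             - y ** 2 / (2.0 * sigma2[:, None] ** 2))
    w = np.exp(log_w - log_w.max(axis=1, keepdims=True))
    wsum = w.sum(axis=1)
    dead = rich & (wsum <= 0)
    alpha = np.zeros(len(points))
    ok = wsum > 0
    alpha[ok] = (w[ok] * y[ok]).sum(axis=1) / wsum[ok]
    alpha[~rich] = 0.0
    alpha[dead] = 0.0
    return points + alpha[:, None] * normals, int(dead.sum())


def bilateral_filter(cloud: PointCloud, field, labels: RegionLabels,
                     params: BilateralParams
                     ) -> tuple[PointCloud, DenoiseReport]:
    """Denoise the rich region; single-region points never move.

    Within one pass every displacement is computed from the pass's input
    positions; between passes the neighbor graph, normals and region labels
    are refreshed so later iterations see the partially smoothed surface.
    """
    if field.normals is None:
        raise ParameterError("bilateral filtering needs estimated normals")
    pts = cloud.points.copy()
    normals = field.normals
    rich = labels.rich
    graph = build_knn(cloud, params.k)
    n_dead = 0
    for it in range(params.iterations):
        if it > 0:
            work = cloud.with_points(pts)
            graph = build_knn(work, params.k)
            fld = estimate_field(work, graph)
            normals = fld.normals
            rich = region_division(fld).rich
        pts, dead = _bilateral_pass(pts, normals, rich, graph)
        n_dead += dead
    out = cloud.with_points(pts)
    report = displacement_metrics(cloud, out)
    return out, report


def laplace_filter(cloud: PointCloud, graph: NeighborhoodGraph,
                   lambda_step: float = 0.5, iterations: int = 1
                   ) -> tuple[PointCloud, DenoiseReport]:
    """Classical umbrella-operator smoothing of every point.

    Each point relaxes toward the average of its neighborhood (the point
    itself plus its k neighbors), scaled by ``lambda_step``; the
    self-inclusive average keeps the full step lambda = 1 contractive
    (two mutual neighbors meet at their midpoint instead of swapping).
    """
    if not (0 < lambda_step <= 1):
        raise ParameterError("lambda_step must lie in (0, 1]")
    if iterations < 1:
        raise ParameterError("iterations must be >= 1")
    pts = cloud.points.copy()
    k = graph.k
    for it in range(iterations):
        if it > 0:
            graph = build_knn(cloud.with_points(pts), k)
        mean_nbr = (pts[graph.indices].sum(axis=1) + pts) / (k + 1)
        pts = pts + lambda_step * (mean_nbr - pts)
    out = cloud.with_points(pts)
    return out, displacement_metrics(cloud, out)


def displacement_metrics(before: PointCloud, after: PointCloud
                         ) -> DenoiseReport:
    """Max and mean per-point movement between two id-aligned clouds."""
    if len(before) != len(after) or not np.array_equal(before.ids, after.ids):
        raise ParameterError("clouds must carry identical ids")
    disp = np.linalg.norm(after.points - before.points, axis=1)
    return DenoiseReport(max_error=float(disp.max()),
                         avg_error=float(disp.mean()),
                         n_moved=int((disp > 0).sum()))


def error_reduction_percent(baseline: float, method: float) -> float:
    """How much smaller a method's error is than a baseline's, in percent."""
    if baseline <= 0:
        raise ParameterError("baseline error must be positive")
    return (baseline - method) / baseline * 100.0
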