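"""Per-point normals and surface-variation curvature from local covariance.

For each point the 3x3 scatter matrix of its neighborhood (the point itself
plus its k nearest neighbors) is eigendecomposed. The eigenvector of the
smallest eigenvalue lambda0 is the local surface normal, and

    sigma = lambda0 / (lambda0 + lambda1 + lambda2)

is the surface variation: 0 on an exact plane, 1/3 for an isotropic blob.
Sigma is scale-free, so it is unchanged by rigid motion and by whether the
scatter matrix is normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NeighborhoodGraph, PointCloud
from .errors import DegenerateNeighborhoodError

__all__ = ["CurvatureField", "local_covariance", "estimate_field"]

_EIG_SUM_TOL = 1e-18


@dataclass
class CurvatureField:
    """Per-point normal, ordered eigenvalue triple and surface variation.

    ``eigenvalues`` rows are sorted ascending (lambda0 <= lambda1 <= lambda2).
    ``degenerate`` flags points whose neighborhood had zero spread; they get
    sigma = 0 and a +z normal.
    """

    normals: np.ndarray
    eigenvalues: np.ndarray
    curvature: np.ndarray
    degenerate: np.ndarray

    def __len__(self) -> int:
        return len(self.curvature)


def local_covariance(neighborhood_points: np.ndarray) -> np.ndarray:
    """Unnormalized scatter matrix sum (p - pbar)(p - pbar)^T of a point set."""
    pts = np.asarray(neighborhood_points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegenerateNeighborhoodError(
            f"covariance needs >= 3 points of dim 3, got shape {pts.shape}")
    centered = pts - pts.mean(axis=0)
    return centered.T @ centered


def estimate_field(cloud: PointCloud, graph: NeighborhoodGraph
                   ) -> CurvatureField:
    """Estimate normals and curvature for every point of ``cloud``.

    Normals are oriented away from the cloud centroid (ties resolved toward
    +z) so repeated runs give identical signs.
    """
    pts = cloud.points
    n = len(pts)
    # (n, k+1, 3) stacked neighborhoods: the point itself plus its neighbors
    hoods = np.concatenate(
        [pts[:, None, :], pts[graph.indices]], axis=1)
    centered = hoods - hoods.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending per row
    eigvals = np.clip(eigvals, 0.0, None)

    total = eigvals.sum(axis=1)
    degenerate = total <= _EIG_SUM_TOL
    sigma = np.zeros(n)
    ok = ~degenerate
    sigma[ok] = eigvals[ok, 0] / total[ok]

    normals = eigvecs[:, :, 0].copy()
    normals[degenerate] = (0.0, 0.0, 1.0)

    # deterministic outward orientation
    outward = pts - pts.mean(axis=0)
    dots = np.einsum("ni,ni->n", normals, outward)
    tie = np.abs(dots) <= 1e-12
    flip = (dots < 0) & ~tie
    flip |= tie & (normals[:, 2] < 0)
    normals[flip] *= -1.0

    return CurvatureField(normals=normals, eigenvalues=eigvals,
                          curvature=sigma, degenerate=degenerate)
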