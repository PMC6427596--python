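"""Core containers: point clouds and k-nearest-neighbor graphs.

Coordinates are millimetres throughout. A :class:`PointCloud` carries stable
integer ids so that points surviving simplification or filtering remain
traceable to the raw scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyCloudError, ParameterError

__all__ = ["PointCloud", "NeighborhoodGraph", "build_knn"]

# Below this size an exact all-pairs scan with full (distance, id) tie
# ordering is cheaper than tree construction and makes determinism trivial.
_BRUTE_FORCE_MAX = 4096


@dataclass
class PointCloud:
    """N x 3 coordinates (mm) with stable ids and optional unit normals."""

    points: np.ndarray
    ids: np.ndarray | None = None
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ParameterError(
                f"points must be (N, 3), got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("point coordinates must be finite")
        if self.ids is None:
            self.ids = np.arange(len(self.points), dtype=np.int64)
        else:
            self.ids = np.asarray(self.ids, dtype=np.int64)
            if self.ids.shape != (len(self.points),):
                raise ParameterError("ids must be one integer per point")
            if len(np.unique(self.ids)) != len(self.ids):
                raise ParameterError("ids must be unique")
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.points.shape:
                raise ParameterError("normals must match points shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ParameterError("normals must be unit length (1e-9)")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask_or_index: np.ndarray) -> "PointCloud":
        """Subset the cloud, preserving ids (and normals when present)."""
        normals = None if self.normals is None else self.normals[mask_or_index]
        return PointCloud(
            self.points[mask_or_index], self.ids[mask_or_index], normals
        )

    def with_points(self, points: np.ndarray) -> "PointCloud":
        """Same ids/normals layout with replaced coordinates."""
        return PointCloud(points, self.ids.copy(),
                          None if self.normals is None else self.normals.copy())


@dataclass
class NeighborhoodGraph:
    """Exact k-nearest neighbors per point, self excluded.

    ``indices``/``distances`` are (N, k) arrays; rows are sorted by
    (distance, neighbor id) so equidistant neighbors resolve to the lower id.
    Entries are positional indices into the cloud that built the graph.
    """

    k: int
    indices: np.ndarray
    distances: np.ndarray
    ids: np.ndarray = field(repr=False)

    def neighbor_ids(self, row: int) -> np.ndarray:
        return self.ids[self.indices[row]]


def build_knn(cloud: PointCloud, k: int) -> NeighborhoodGraph:
    """Exact Euclidean k-NN; ties broken toward the lower point id.

    Raises :class:`ParameterError` when ``k >= N`` (a point cannot neighbor
    itself) or ``k < 1``.
    """
    n = len(cloud)
    if n == 0:
        raise EmptyCloudError("cannot build a neighbor graph on 0 points")
    if k < 1 or k >= n:
        raise ParameterError(f"k must satisfy 1 <= k < N (k={k}, N={n})")

    pts = cloud.points
    if n <= _BRUTE_FORCE_MAX:
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
        np.fill_diagonal(d2, np.inf)
        # lexsort: primary key distance, secondary key id
        order = np.lexsort((np.broadcast_to(cloud.ids, d2.shape), d2), axis=1)
        idx = order[:, :k]
        dist = np.sqrt(np.take_along_axis(d2, idx, axis=1))
    else:
        tree = cKDTree(pts)
        # query a few extra candidates so boundary ties can be re-ranked
        m = min(n, k + 8)
        dist_c, idx_c = tree.query(pts, k=m + 1)
        rows = np.arange(n)[:, None]
        self_mask = idx_c == rows
        # keep the first m non-self candidates per row
        dist_list = np.where(self_mask, np.inf, dist_c)
        order = np.lexsort((cloud.ids[idx_c], dist_list), axis=1)
        idx = np.take_along_axis(idx_c, order, axis=1)[:, :k]
        dist = np.take_along_axis(dist_list, order, axis=1)[:, :k]
    return NeighborhoodGraph(k=k, indices=idx, distances=dist, ids=cloud.ids)
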