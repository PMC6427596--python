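"""Curvature-adaptive grid simplification.

The cloud is binned into a uniform grid whose base cell size

    D = gamma * (Xbox * Ybox * Zbox / N) ** (1/3)

derives from the bounding-box volume per point (a mean-spacing scale).
Cells whose mean surface variation exceeds the cloud-wide mean are "detail"
cells; the rest are "non-detail". Each class is then re-binned at
``beta * D`` (a small beta for detail regions, a larger one for flat
regions) and a single representative point — the member nearest its
sub-cell's member centroid — survives per occupied sub-cell. Survivors are
original points; coordinates are never averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import PointCloud
from .errors import EmptyCloudError, ParameterError
from .geometry import CurvatureField

__all__ = [
    "GridModel", "SimplifiedCloud", "bounding_box", "base_cell_size",
    "build_grid", "classify_cells", "simplify", "simplification_rate",
    "RESOLUTION_FLOOR_MM",
]

#: Flat (zero-extent) dimensions are inflated to this scanner resolution
#: floor before the cell-size formula, which needs a positive volume.
RESOLUTION_FLOOR_MM = 0.178


@dataclass
class GridModel:
    """Uniform grid over a cloud with per-cell curvature labels."""

    extents: np.ndarray
    base_cell: float
    gamma: float
    beta_detail: float
    beta_nondetail: float
    cells: dict  # (i, j, k) -> array of positional point indices
    origin: np.ndarray
    cell_mean_curvature: dict = field(default_factory=dict)
    curvature_threshold: float | None = None
    cell_labels: dict = field(default_factory=dict)  # (i,j,k) -> "detail"|...


@dataclass
class SimplifiedCloud:
    cloud: PointCloud
    kept_ids: np.ndarray
    rate_percent: float
    n_detail_cells: int = 0
    n_nondetail_cells: int = 0


def bounding_box(cloud: PointCloud) -> np.ndarray:
    """Axis-aligned extents (max - min) per coordinate, in mm."""
    if len(cloud) == 0:
        raise EmptyCloudError("bounding box of an empty cloud")
    return cloud.points.max(axis=0) - cloud.points.min(axis=0)


def base_cell_size(extents: np.ndarray, n_points: int, gamma: float) -> float:
    """Base grid cell size D = gamma * (volume per point) ** (1/3)."""
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    if n_points < 1:
        raise ParameterError("n_points must be >= 1")
    ext = np.asarray(extents, dtype=np.float64).copy()
    if np.any(ext < 0):
        raise ParameterError("extents must be non-negative")
    if np.any(ext == 0):
        warnings.warn(
            "zero extent inflated to the resolution floor "
            f"({RESOLUTION_FLOOR_MM} mm)", stacklevel=2)
        ext[ext == 0] = RESOLUTION_FLOOR_MM
    return float(gamma * (np.prod(ext) / n_points) ** (1.0 / 3.0))


def _cell_indices(points: np.ndarray, origin: np.ndarray, cell: float,
                  n_cells: np.ndarray) -> np.ndarray:
    idx = np.floor((points - origin) / cell).astype(np.int64)
    return np.clip(idx, 0, n_cells - 1)


def build_grid(cloud: PointCloud, gamma: float = 0.1,
               beta_detail: float = 1.0, beta_nondetail: float = 2.0
               ) -> GridModel:
    """Bin the cloud into half-open cells of the base size D."""
    ext = bounding_box(cloud)
    d = base_cell_size(ext, len(cloud), gamma)
    origin = cloud.points.min(axis=0)
    n_cells = np.maximum(1, np.ceil(ext / d).astype(np.int64))
    idx = _cell_indices(cloud.points, origin, d, n_cells)
    cells: dict = {}
    keys = [tuple(row) for row in idx]
    order = np.argsort(
        idx[:, 0] * n_cells[1] * n_cells[2] + idx[:, 1] * n_cells[2]
        + idx[:, 2], kind="stable")
    start = 0
    for pos in range(1, len(order) + 1):
        if pos == len(order) or keys[order[pos]] != keys[order[start]]:
            cells[keys[order[start]]] = np.sort(order[start:pos])
            start = pos
    return GridModel(extents=ext, base_cell=d, gamma=gamma,
                     beta_detail=beta_detail, beta_nondetail=beta_nondetail,
                     cells=cells, origin=origin)


def classify_cells(grid: GridModel, field: CurvatureField) -> GridModel:
    """Label every occupied cell detail / non-detail by mean curvature.

    The global threshold is the mean surface variation over the whole
    cloud; a cell is detail iff its member mean strictly exceeds it.
    """
    sigma = field.curvature
    thr = float(sigma.mean())
    grid.curvature_threshold = thr
    for key, members in grid.cells.items():
        di = float(sigma[members].mean())
        grid.cell_mean_curvature[key] = di
        # tolerance absorbs float summation noise when all sigma are equal
        is_detail = di > thr and not np.isclose(di, thr, rtol=1e-9,
                                                atol=1e-15)
        grid.cell_labels[key] = "detail" if is_detail else "non-detail"
    return grid


def _pick_representatives(points: np.ndarray, ids: np.ndarray,
                          member_pos: np.ndarray, origin: np.ndarray,
                          cell: float) -> np.ndarray:
    """One survivor per occupied sub-cell: nearest the member centroid,
    ties toward the lower id. Returns positional indices."""
    pts = points[member_pos]
    idx = np.floor((pts - origin) / cell).astype(np.int64)
    idx -= idx.min(axis=0)
    key = (idx[:, 0].astype(np.int64) * (idx[:, 1].max() + 1)
           + idx[:, 1]) * (idx[:, 2].max() + 1) + idx[:, 2]
    uniq, inv = np.unique(key, return_inverse=True)
    sums = np.zeros((len(uniq), 3))
    np.add.at(sums, inv, pts)
    counts = np.bincount(inv, minlength=len(uniq))
    centroids = sums / counts[:, None]
    dist = np.linalg.norm(pts - centroids[inv], axis=1)
    order = np.lexsort((ids[member_pos], dist, inv))
    first = np.ones(len(order), dtype=bool)
    first[1:] = inv[order[1:]] != inv[order[:-1]]
    return member_pos[order[first]]


def simplify(cloud: PointCloud, field: CurvatureField, gamma: float = 0.1,
             beta_detail: float = 1.0, beta_nondetail: float = 2.0
             ) -> SimplifiedCloud:
    """Adaptive-density simplification driven by the curvature field."""
    if not (0 < beta_detail < beta_nondetail):
        raise ParameterError(
            "betas must satisfy 0 < beta_detail < beta_nondetail")
    if len(field) != len(cloud):
        raise ParameterError("curvature field does not match cloud")
    grid = build_grid(cloud, gamma, beta_detail, beta_nondetail)
    classify_cells(grid, field)

    # partition check: every point in exactly one cell
    total = sum(len(m) for m in grid.cells.values())
    assert total == len(cloud), "grid cells must partition the cloud"

    detail_pos, nondetail_pos = [], []
    for key, members in grid.cells.items():
        (detail_pos if grid.cell_labels[key] == "detail"
         else nondetail_pos).append(members)
    keep = []
    for positions, beta in ((detail_pos, beta_detail),
                            (nondetail_pos, beta_nondetail)):
        if positions:
            pos = np.concatenate(positions)
            keep.append(_pick_representatives(
                cloud.points, cloud.ids, pos, grid.origin,
                beta * grid.base_cell))
    keep_pos = np.sort(np.concatenate(keep))
    out = cloud.select(keep_pos)
    rate = simplification_rate(len(cloud), len(out))
    labels = list(grid.cell_labels.values())
    return SimplifiedCloud(
        cloud=out, kept_ids=out.ids.copy(), rate_percent=rate,
        n_detail_cells=labels.count("detail"),
        n_nondetail_cells=labels.count("non-detail"))


def simplification_rate(p_raw: int, p_kept: int) -> float:
    """Percentage of points removed, relative to the raw count."""
    if p_kept <= 0 or p_raw <= 0:
        raise ParameterError("point counts must be positive")
    if p_kept > p_raw:
        raise ParameterError("kept count exceeds raw count")
    return (p_raw - p_kept) / p_raw * 100.0
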