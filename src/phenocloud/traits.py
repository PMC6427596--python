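"""Phenotypic traits from a cleaned single-plant cloud.

Plant height and canopy breadth come from a "fitting sphere" whose center is
an extreme canopy point: the sphere radius — the distance to the opposing
extreme point — is the trait. Stem diameter comes from a least-squares
cylinder fitted to a stem slab (the third internode when its height window
is known). The vertical axis defaults to y and the breadth axis to x,
matching the scanner convention the pipeline assumes; both are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import least_squares

from .core import PointCloud
from .errors import (DegenerateGeometryError, EmptyCloudError,
                     InsufficientStemPointsError, ParameterError)

__all__ = [
    "SphereFit", "CylinderFit", "TraitReport", "fit_sphere", "fit_cylinder",
    "plant_height", "stem_diameter", "canopy_breadth", "compute_traits",
]

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int


@dataclass
class CylinderFit:
    axis_point: np.ndarray
    axis_dir: np.ndarray
    radius: float
    rms_residual: float
    n_points: int
    converged: bool = True


@dataclass
class TraitReport:
    plant_height: float
    stem_diameter: float
    canopy_breadth: float
    vertical_axis: str = "y"
    breadth_axis: str = "x"
    stem_window: tuple | None = None
    diagnostics: dict = dc_field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "plant_height_mm": self.plant_height,
            "stem_diameter_mm": self.stem_diameter,
            "canopy_breadth_mm": self.canopy_breadth,
            "vertical_axis": self.vertical_axis,
            "breadth_axis": self.breadth_axis,
            "stem_window_mm": (None if self.stem_window is None
                               else list(self.stem_window)),
            "diagnostics": self.diagnostics,
        }


def _axis_index(axis: str) -> int:
    try:
        return _AXIS[axis]
    except KeyError:
        raise ParameterError(f"axis must be one of x/y/z, got {axis!r}")


def fit_sphere(points: np.ndarray) -> SphereFit:
    """Least-squares sphere: algebraic initialization, geometric refinement.

    Minimizes sum (||c - P_i|| - r)^2. The linear (algebraic) solve of
    ||P||^2 = 2 c.P + (r^2 - c.c) seeds a Levenberg-Marquardt refinement of
    the true geometric distance residual.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise DegenerateGeometryError("sphere fit needs >= 4 points")
    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts ** 2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError(
            "points are coplanar or otherwise rank-deficient for a sphere")
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 0.0)))

    def resid(p):
        return np.linalg.norm(pts - p[:3], axis=1) - p[3]

    res = least_squares(resid, np.append(c0, r0), method="trf",
                        gtol=1e-15, xtol=1e-15, ftol=1e-15, max_nfev=100 * 5)
    c = res.x[:3]
    r = abs(float(res.x[3]))
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return SphereFit(center=c, radius=r, rms_residual=rms, n_points=len(pts))


def fit_cylinder(points: np.ndarray, init: tuple | None = None
                 ) -> CylinderFit:
    """Least-squares cylinder with free axis, point and radius.

    Residual per point is d_i - r with
    d_i = sqrt(||q0 - P_i||^2 - (a0 . (q0 - P_i))^2), the distance to the
    axis line. Initialization uses the centroid, the principal scatter axis
    and the mean radial distance unless ``init=(q0, a0, r)`` is given. The
    reported axis point is the projection of q0 onto the plane through the
    centroid normal to the axis (the axis position is otherwise
    unidentifiable along itself).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 6:
        raise DegenerateGeometryError("cylinder fit needs >= 6 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 1e-12 * max(evals[2], 1.0):
        raise DegenerateGeometryError("points are (near-)collinear")
    if init is None:
        a0 = evecs[:, 2]
        q0 = centroid
        d = _axis_distances(pts, q0, a0)
        r0 = float(d.mean())
        if r0 <= 0:
            r0 = 1.0
    else:
        q0, a0, r0 = (np.asarray(init[0], float),
                      np.asarray(init[1], float), float(init[2]))
        a0 = a0 / np.linalg.norm(a0)

    def resid(p):
        q, w, r = p[:3], p[3:6], p[6]
        w = w / np.linalg.norm(w)
        return _axis_distances(pts, q, w) - r

    x0 = np.concatenate([q0, a0, [r0]])
    res = least_squares(resid, x0, method="trf", gtol=1e-15, xtol=1e-15,
                        ftol=1e-15, max_nfev=200 * 8)
    q = res.x[:3]
    a = res.x[3:6] / np.linalg.norm(res.x[3:6])
    r = abs(float(res.x[6]))
    converged = res.status > 0 and res.nfev < 200 * 8
    if not converged:
        warnings.warn("cylinder fit did not converge", stacklevel=2)
    # gauge fix: slide q along the axis into the centroid-normal plane
    q = q + ((centroid - q) @ a) * a
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return CylinderFit(axis_point=q, axis_dir=a, radius=r, rms_residual=rms,
                       n_points=len(pts), converged=converged)


def _axis_distances(pts: np.ndarray, q: np.ndarray, a: np.ndarray
                    ) -> np.ndarray:
    delta = q - pts
    proj = delta @ a
    return np.sqrt(np.maximum(np.sum(delta ** 2, axis=1) - proj ** 2, 0.0))


def plant_height(cloud: PointCloud, vertical_axis: str = "y",
                 apex_quantile: float = 1.0, search_radius: float = 30.0
                 ) -> tuple[float, SphereFit]:
    """Apex-to-base distance: the radius of a sphere centred on the apex.

    The apex is the point at ``apex_quantile`` of the vertical coordinate
    (1.0 = the literal highest point; slightly lower quantiles reject
    spike outliers). The base is the lowest point within ``search_radius``
    of the apex's vertical line, falling back to the global minimum when
    that cylinder is empty.
    """
    if len(cloud) == 0:
        raise EmptyCloudError("plant height of an empty cloud")
    if not (0 < apex_quantile <= 1):
        raise ParameterError("apex_quantile must lie in (0, 1]")
    ai = _axis_index(vertical_axis)
    v = cloud.points[:, ai]
    order = np.lexsort((cloud.ids, v))
    rank = int(round(apex_quantile * (len(v) - 1)))
    apex = cloud.points[order[rank]]

    horiz = np.delete(cloud.points, ai, axis=1)
    apex_h = np.delete(apex, ai)
    in_cyl = np.linalg.norm(horiz - apex_h, axis=1) <= search_radius
    if np.any(in_cyl):
        cand = np.where(in_cyl)[0]
    else:
        cand = np.arange(len(v))
    base = cloud.points[cand[np.lexsort((cloud.ids[cand], v[cand]))[0]]]
    height = float(np.linalg.norm(apex - base))
    return height, SphereFit(center=apex.copy(), radius=height,
                             rms_residual=0.0, n_points=2)


def stem_diameter(cloud: PointCloud, vertical_axis: str = "y",
                  stem_window: tuple | None = None,
                  r_gate_factor: float = 3.0,
                  base_band_fraction: float = 0.08
                  ) -> tuple[float, CylinderFit]:
    """Cylinder diameter of the stem slab inside a height window.

    Without a window a heuristic [0.2 H, 0.35 H] band above the plant base
    is used — a stand-in for locating the third internode, which the cloud
    alone does not identify. Leaves crossing the window can dominate the
    slab, so the stem's vertical center line is anchored on the base band
    (the lowest ``base_band_fraction`` of the height range, which is leaf-
    free on a rooted plant); slab points further than ``r_gate_factor``
    times the base band's median radial distance from that line are
    discarded before fitting.
    """
    if len(cloud) == 0:
        raise EmptyCloudError("stem diameter of an empty cloud")
    ai = _axis_index(vertical_axis)
    v = cloud.points[:, ai]
    vmin, vmax = float(v.min()), float(v.max())
    if stem_window is None:
        h = vmax - vmin
        stem_window = (vmin + 0.20 * h, vmin + 0.35 * h)
    low, high = float(stem_window[0]), float(stem_window[1])
    if not low < high:
        raise ParameterError("stem_window must satisfy low < high")
    slab = (v >= low) & (v <= high)
    n_window = int(slab.sum())
    if n_window < 6:
        raise InsufficientStemPointsError(n_window, 0)

    pts = cloud.points[slab]
    horiz = np.delete(pts, ai, axis=1)
    base_band = v <= vmin + base_band_fraction * max(vmax - vmin, 1e-9)
    if base_band.sum() >= 6:
        base_h = np.delete(cloud.points[base_band], ai, axis=1)
        center_h = base_h.mean(axis=0)
        r_scale = float(np.median(np.linalg.norm(base_h - center_h, axis=1)))
    else:
        center_h = horiz.mean(axis=0)
        r_scale = 0.0
    radial = np.linalg.norm(horiz - center_h, axis=1)
    if r_scale <= 0:
        r_scale = float(np.median(radial))
    gate = r_gate_factor * r_scale
    gated = radial <= gate
    n_gated = int(gated.sum())
    if n_gated < 6:
        raise InsufficientStemPointsError(n_window, n_gated)

    axis0 = np.zeros(3)
    axis0[ai] = 1.0
    q0 = pts[gated].mean(axis=0)
    r0 = float(np.median(radial[gated]))
    fit = fit_cylinder(pts[gated], init=(q0, axis0, r0))
    return 2.0 * fit.radius, fit


def canopy_breadth(cloud: PointCloud, breadth_axis: str = "x",
                   height_tolerance: float = 10.0,
                   vertical_axis: str = "y") -> tuple[float, dict]:
    """Distance from the leftmost canopy point to the farthest point at
    (approximately) the same height — the radius of a sphere centred on
    the leftmost point.

    Falls back to the plain extent along the breadth axis (with a warning)
    when no second point shares the center's height band.
    """
    if len(cloud) == 0:
        raise EmptyCloudError("canopy breadth of an empty cloud")
    bi = _axis_index(breadth_axis)
    vi = _axis_index(vertical_axis)
    if bi == vi:
        raise ParameterError("breadth and vertical axes must differ")
    b = cloud.points[:, bi]
    center_idx = int(np.lexsort((cloud.ids, b))[0])
    center = cloud.points[center_idx]
    near = np.abs(cloud.points[:, vi] - center[vi]) <= height_tolerance
    diag = {"center": center.copy(), "n_candidates": int(near.sum()),
            "fallback": False}
    if near.sum() < 2:
        warnings.warn("no canopy point at the leftmost point's height; "
                      "falling back to the breadth-axis extent", stacklevel=2)
        diag["fallback"] = True
        return float(b.max() - b.min()), diag
    dists = np.linalg.norm(cloud.points[near] - center, axis=1)
    return float(dists.max()), diag


def compute_traits(cloud: PointCloud, vertical_axis: str = "y",
                   breadth_axis: str = "x", stem_window: tuple | None = None,
                   apex_quantile: float = 1.0, search_radius: float = 30.0,
                   height_tolerance: float = 10.0,
                   r_gate_factor: float = 3.0) -> TraitReport:
    """All three traits in one report, with fit diagnostics."""
    height, hfit = plant_height(cloud, vertical_axis, apex_quantile,
                                search_radius)
    diam, cfit = stem_diameter(cloud, vertical_axis, stem_window,
                               r_gate_factor)
    breadth, bdiag = canopy_breadth(cloud, breadth_axis, height_tolerance,
                                    vertical_axis)
    diagnostics = {
        "height_apex": hfit.center.tolist(),
        "stem_fit": {
            "radius_mm": cfit.radius,
            "axis_dir": cfit.axis_dir.tolist(),
            "rms_residual_mm": cfit.rms_residual,
            "n_points": cfit.n_points,
            "converged": cfit.converged,
        },
        "breadth_center": bdiag["center"].tolist(),
        "breadth_fallback": bdiag["fallback"],
    }
    return TraitReport(plant_height=height, stem_diameter=diam,
                       canopy_breadth=breadth, vertical_axis=vertical_axis,
                       breadth_axis=breadth_axis, stem_window=stem_window,
                       diagnostics=diagnostics)
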