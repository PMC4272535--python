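"""Minimum-area enclosing shapes used by the fuzzy shape descriptors.

The triangular/rectangular/circular similarity of a detected entity is the
ratio of its area to the area of the smallest triangle, rotated rectangle or
circle that encloses it, so the three enclosure problems are solved exactly:

* triangle -- own implementation (below); no established Python geometry
  library provides it.  It enumerates the finitely many support-line
  configurations that can realise a local optimum: one side flush with a hull
  edge (a classical necessary condition for the global optimum), each other
  side either flush with an edge or touching a hull vertex at its midpoint
  (the midpoint-touching optimality condition).  The minimum over all valid
  (hull-containing) candidates is the exact optimum.
* rectangle -- rotating-calipers oriented envelope (shapely).
* circle -- minimum bounding circle (shapely).
"""

from __future__ import annotations

import math

import numpy as np
import shapely
from shapely.geometry import MultiPoint

__all__ = [
    "convex_hull_vertices",
    "min_enclosing_triangle",
    "min_enclosing_rectangle_area",
    "min_enclosing_circle",
]


def convex_hull_vertices(points) -> np.ndarray:
    """Convex hull of a point set as a CCW vertex array (no repeated endpoint).

    Returns fewer than 3 vertices when the hull degenerates to a point or a
    segment.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type == "Point":
        return np.array([[hull.x, hull.y]])
    if hull.geom_type == "LineString":
        return np.asarray(hull.coords)
    coords = np.asarray(hull.exterior.coords)[:-1]
    return coords


def _intersect_lines(p1, d1, p2, d2):
    """Intersection of lines p1 + t d1 and p2 + s d2 (nan when parallel)."""
    denom = d1[..., 0] * d2[..., 1] - d1[..., 1] * d2[..., 0]
    diff = p2 - p1
    num = diff[..., 0] * d2[..., 1] - diff[..., 1] * d2[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    return p1 + t[..., None] * d1


def _triangle_areas(v1, v2, v3):
    return 0.5 * np.abs(
        (v2[..., 0] - v1[..., 0]) * (v3[..., 1] - v1[..., 1])
        - (v2[..., 1] - v1[..., 1]) * (v3[..., 0] - v1[..., 0])
    )


def _contains_all(v1, v2, v3, points, tol):
    """Whether the triangles (v1,v2,v3) contain every point (broadcast batch)."""

    def side(a, b):
        # cross((b - a), (points - a)) for all points -> (..., npts)
        ab = b - a
        ap = points[None, :, :] - a[..., None, :] if a.ndim == 2 else points - a
        return ab[..., None, 0] * ap[..., 1] - ab[..., None, 1] * ap[..., 0]

    s1 = side(v1, v2)
    s2 = side(v2, v3)
    s3 = side(v3, v1)
    pos = (s1 >= -tol).all(axis=-1) & (s2 >= -tol).all(axis=-1) & (s3 >= -tol).all(axis=-1)
    neg = (s1 <= tol).all(axis=-1) & (s2 <= tol).all(axis=-1) & (s3 <= tol).all(axis=-1)
    return pos | neg


def min_enclosing_triangle(points) -> tuple[float, np.ndarray | None]:
    """Exact minimum-area triangle enclosing a point set.

    Returns ``(area, vertices)``; ``(0.0, None)`` when the hull is degenerate
    (fewer than 3 non-collinear points).
    """
    hull = convex_hull_vertices(points)
    h = len(hull)
    if h < 3:
        return 0.0, None
    scale = max(hull.max() - hull.min(), 1.0)
    tol = 1e-9 * scale

    e0 = hull                      # edge start points
    ed = np.roll(hull, -1, axis=0) - hull  # edge direction vectors

    best_area = math.inf
    best_tri = None

    # parallel-line intersections intentionally produce nan candidates
    np_err = np.errstate(divide="ignore", invalid="ignore")
    np_err.__enter__()
    for i in range(h):
        c0, cd = e0[i], ed[i]

        # side C = base line i; candidate A/B lines flush with every edge
        v_ca = _intersect_lines(c0[None, :], cd[None, :], e0, ed)  # (h, 2)

        # --- flush x flush candidates -------------------------------------
        vab = _intersect_lines(e0[:, None, :], ed[:, None, :],
                               e0[None, :, :], ed[None, :, :])     # (h, h, 2)
        v1 = v_ca[:, None, :] + np.zeros((h, h, 2))  # C ^ A_j
        v2 = np.broadcast_to(v_ca[None, :, :], (h, h, 2)).copy()  # C ^ B_k
        _consider(v1, v2, vab, hull, tol, best := [best_area, best_tri])
        best_area, best_tri = best

        # --- flush A_j x midpoint-vertex v --------------------------------
        # B meets base at p and A_j at q with the vertex at the midpoint.
        a0 = e0[:, None, :]  # (h,1,2) line A_j
        ad = ed[:, None, :]
        verts = hull[None, :, :]  # (1,h,2)
        denom = cd[0] * ad[..., 1] - cd[1] * ad[..., 0]  # cross(cd, ad) (h,1)
        rhs = 2.0 * verts - c0 - a0
        num = rhs[..., 0] * ad[..., 1] - rhs[..., 1] * ad[..., 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / denom
        p = c0 + t[..., None] * cd              # on base line C
        q = 2.0 * verts - p                     # on line A_j
        w = np.broadcast_to(v_ca[:, None, :], p.shape).copy()  # C ^ A_j
        _consider(w, p, q, hull, tol, best := [best_area, best_tri])
        best_area, best_tri = best
    np_err.__exit__(None, None, None)

    return best_area, best_tri


def _consider(v1, v2, v3, hull, tol, best):
    areas = _triangle_areas(v1, v2, v3)
    finite = np.isfinite(areas) & np.isfinite(v1).all(axis=-1) \
        & np.isfinite(v2).all(axis=-1) & np.isfinite(v3).all(axis=-1)
    areas = np.where(finite & (areas > tol), areas, np.inf)
    if not np.isfinite(areas).any():
        return
    # cheap pre-filter: only triangles that could improve the best
    cand = areas < best[0]
    if not cand.any():
        return
    idx = np.argwhere(cand)
    v1c = v1[tuple(idx.T)]
    v2c = v2[tuple(idx.T)]
    v3c = v3[tuple(idx.T)]
    ok = _contains_all(v1c, v2c, v3c, hull, tol)
    if not ok.any():
        return
    areas_ok = areas[tuple(idx.T)][ok]
    k = int(np.argmin(areas_ok))
    if areas_ok[k] < best[0]:
        best[0] = float(areas_ok[k])
        best[1] = np.stack([v1c[ok][k], v2c[ok][k], v3c[ok][k]])


def min_enclosing_rectangle_area(points) -> float:
    """Area of the minimum-area (rotated) rectangle enclosing the points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    env = shapely.oriented_envelope(MultiPoint(pts))
    return float(env.area)


def min_enclosing_circle(points) -> tuple[float, float]:
    """(radius, area) of the minimum enclosing circle of the points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    r = float(shapely.minimum_bounding_radius(MultiPoint(pts)))
    return r, math.pi * r * r
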