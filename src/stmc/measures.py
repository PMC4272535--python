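"""The eleven spatial measures for regions, clusters and collections.

Every detected entity is summarised by: clusteredness, density, area,
perimeter, distance from the origin (the centre of the discretised space),
angle subtended at the origin, the three fuzzy shape measures
(triangular/rectangular/circular), and the centroid coordinates.  The same
vocabulary is shared by the STML format and the spatio-temporal logic, so
these functions emit :class:`~stmc.stml.SpatialEntityRecord` objects directly.

Conventions for degenerate inputs (polygons of zero area, singleton groups)
are documented on each function; they keep all values finite and inside the
ranges the STML schema enforces.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from shapely.geometry import Point

from . import geometry
from .errors import ParameterError
from .patterns import Cluster, Region, _polygon_area_centroid, centroid_distance
from .stml import SpatialEntityRecord

__all__ = [
    "SpaceGeometry",
    "CollectionStatistics",
    "region_measures",
    "cluster_measures",
    "collection_statistics",
    "shape_measure",
    "shape_measures",
    "angle_degrees",
    "silhouette_index",
]


@dataclass(frozen=True)
class SpaceGeometry:
    """Dimensions of the discretised space; the origin is its centre point."""

    rows: int
    cols: int

    @property
    def origin(self) -> tuple[float, float]:
        return ((self.cols - 1) / 2.0, (self.rows - 1) / 2.0)


@dataclass(frozen=True)
class CollectionStatistics:
    """Group-level clusteredness and density of a set of entities."""

    clusteredness: float
    density: float


def _polyline_length(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float).reshape(-1, 2)
    if len(v) < 2:
        return 0.0
    closed = np.vstack([v, v[:1]])
    return float(np.hypot(*np.diff(closed, axis=0).T).sum())


def _shoelace_area(vertices: np.ndarray) -> float:
    return _polygon_area_centroid(np.asarray(vertices, dtype=float).reshape(-1, 2))[0]


def shape_measure(polygon, shape: str) -> float:
    """Fuzzy likelihood in [0, 1] that *polygon* has the given basic shape.

    ``area(polygon) / area(minimum-area enclosing <shape> polygon)``; 0 for
    polygons without positive area.
    """
    vertices = np.asarray(polygon, dtype=float).reshape(-1, 2)
    area = _shoelace_area(vertices)
    if area <= 0:
        return 0.0
    if shape == "triangular":
        enclosing, _ = geometry.min_enclosing_triangle(vertices)
    elif shape == "rectangular":
        enclosing = geometry.min_enclosing_rectangle_area(vertices)
    elif shape == "circular":
        enclosing = geometry.min_enclosing_circle(vertices)[1]
    else:
        raise ParameterError(f"unknown shape {shape!r}")
    if not np.isfinite(enclosing) or enclosing <= 0:
        return 0.0
    return float(min(1.0, area / enclosing))


def shape_measures(polygon) -> tuple[float, float, float, str]:
    """All three shape measures plus the winning shape name.

    Ties resolve in the fixed order triangular > rectangular > circular.
    """
    tri = shape_measure(polygon, "triangular")
    rect = shape_measure(polygon, "rectangular")
    circ = shape_measure(polygon, "circular")
    best = max(tri, rect, circ)
    if tri >= best:
        name = "triangular"
    elif rect >= best:
        name = "rectangular"
    else:
        name = "circular"
    return tri, rect, circ, name


def angle_degrees(polygon, geom: SpaceGeometry) -> float:
    """Angle (degrees) subtended at the origin by the entity's convex hull.

    The hull is cut with the line through the entity centroid perpendicular
    to the origin-centroid segment; the returned value is the angle between
    the two extreme intersection points as seen from the origin.  360 when
    the origin lies inside the hull, 0 for point-like hulls or when the
    centroid coincides with the origin.
    """
    vertices = np.asarray(polygon, dtype=float).reshape(-1, 2)
    hull = geometry.convex_hull_vertices(vertices)
    if len(hull) < 2:
        return 0.0
    px, py = geom.origin
    p = np.array([px, py])
    from shapely.geometry import LineString, MultiPoint

    hull_geom = MultiPoint(hull).convex_hull
    if hull_geom.covers(Point(px, py)):
        return 360.0
    _, centroid = _polygon_area_centroid(vertices)
    c = np.array(centroid)
    pc = c - p
    norm = np.hypot(*pc)
    if norm < 1e-12:
        return 0.0
    w = np.array([-pc[1], pc[0]]) / norm  # unit perpendicular
    reach = float(np.abs(hull - c).max() * 4 + norm + 1.0)
    cut = LineString([c - reach * w, c + reach * w])
    inter = hull_geom.intersection(cut)
    if inter.is_empty:
        return 0.0
    coords = np.asarray(
        [pt for g in getattr(inter, "geoms", [inter]) for pt in g.coords]
    )
    proj = coords @ w
    a = coords[np.argmin(proj)]
    b = coords[np.argmax(proj)]
    va, vb = a - p, b - p
    dot = float(va @ vb)
    cross = float(va[0] * vb[1] - va[1] * vb[0])
    return float(np.degrees(np.arctan2(abs(cross), dot)))


def _distance_from_origin(entity_geom, geom: SpaceGeometry) -> float:
    return float(entity_geom.distance(Point(*geom.origin)))


def _measures_for_polygon(outer, geom: SpaceGeometry,
                          distance_geom) -> dict:
    """Perimeter, distance, angle, shape measures and centroid for a boundary."""
    outer = np.asarray(outer, dtype=float).reshape(-1, 2)
    area, centroid = _polygon_area_centroid(outer)
    tri, rect, circ, shape = shape_measures(outer)
    return {
        "perimeter": _polyline_length(outer),
        "distanceFromOrigin": _distance_from_origin(distance_geom, geom),
        "angle": angle_degrees(outer, geom),
        "triangularMeasure": tri,
        "rectangularMeasure": rect,
        "circularMeasure": circ,
        "shape": shape,
        "centroidX": float(centroid[0]),
        "centroidY": float(centroid[1]),
    }


def _positions_density(positions, grid) -> float:
    if not positions:
        return 0.0
    grid = np.asarray(grid, dtype=float)
    rows, cols = zip(*positions)
    return float(grid[list(rows), list(cols)].mean())


def region_measures(region: Region, grid, geom: SpaceGeometry) -> SpatialEntityRecord:
    """All eleven spatial measures of one region.

    Clusteredness is ``area / (area + total hole area)`` (1 for hole-free
    regions); density the mean grid value over the covered pixels; area the
    outer-polygon area minus hole areas; the perimeter ignores holes.  Shape
    measures are computed on the outer boundary.  Degenerate (area-0)
    boundaries fall back to the pixel set: area 0, shape measures 0,
    clusteredness 1, centroid = pixel mean.
    """
    hole_area = float(sum(_shoelace_area(h) for h in region.holes))
    outer_area = region.outer_area
    net_area = max(0.0, outer_area - hole_area)
    if outer_area > 0:
        clusteredness = net_area / (net_area + hole_area)
    else:
        clusteredness = 1.0
    m = _measures_for_polygon(region.outer_contour, geom, region.outer_polygon())
    if outer_area == 0.0 and region.positions:
        c = region.centroid
        m["centroidX"], m["centroidY"] = float(c[0]), float(c[1])
    return SpatialEntityRecord(
        entityType="region",
        clusteredness=clusteredness,
        density=_positions_density(region.positions, grid),
        area=net_area,
        **m,
    )


def _mean_pairwise_distance(entities) -> float:
    """Mean pairwise centroid distance; 1.0 for fewer than two entities.

    The singleton convention keeps group clusteredness/density finite and
    equal to the member value for one-entity groups.
    """
    if len(entities) < 2:
        return 1.0
    dists = [centroid_distance(a, b) for a, b in combinations(entities, 2)]
    return float(np.mean(dists))


def cluster_measures(cluster: Cluster, grid, geom: SpaceGeometry) -> SpatialEntityRecord:
    """All eleven spatial measures of one cluster of regions.

    Clusteredness is the inverse mean pairwise centroid distance of the
    members (1 for single-member clusters); density the mean grid value over
    all member pixels pooled; area/perimeter/distance/angle/shape/centroid
    are computed on the convex hull of all member regions (holes between
    regions are ignored).  A hull degenerating to a segment has area 0 and
    perimeter twice its length.
    """
    if not cluster.members:
        raise ParameterError("cluster must contain at least one region")
    mean_dist = _mean_pairwise_distance(cluster.members)
    clusteredness = 1.0 / mean_dist if mean_dist > 1e-12 else 1.0
    positions = set()
    for member in cluster.members:
        positions |= set(member.positions)
    hull = geometry.convex_hull_vertices(
        np.vstack([m.outer_contour for m in cluster.members])
    )
    from shapely.geometry import MultiPoint

    hull_geom = MultiPoint(hull).convex_hull
    m = _measures_for_polygon(hull, geom, hull_geom)
    if len(hull) < 3 or _shoelace_area(hull) == 0.0:
        cents = np.array([mem.centroid for mem in cluster.members])
        if _shoelace_area(hull) == 0.0 and len(hull) >= 2:
            mid = hull.mean(axis=0)
            m["centroidX"], m["centroidY"] = float(mid[0]), float(mid[1])
        else:
            m["centroidX"], m["centroidY"] = map(float, cents.mean(axis=0))
    return SpatialEntityRecord(
        entityType="cluster",
        clusteredness=clusteredness,
        density=_positions_density(positions, grid),
        area=_shoelace_area(hull),
        **m,
    )


def collection_statistics(entities, grid, geom: SpaceGeometry) -> CollectionStatistics:
    """Group-level clusteredness and density of a set of regions or clusters.

    Clusteredness of the set is the inverse mean pairwise centroid distance;
    density is the mean member density divided by the same mean distance.
    Sets with fewer than two members use divisor 1; the empty set has
    clusteredness 1 and density 0.
    """
    mean_dist = _mean_pairwise_distance(entities)
    if mean_dist <= 1e-12:
        mean_dist = 1.0
    if not entities:
        return CollectionStatistics(clusteredness=1.0, density=0.0)
    densities = []
    for e in entities:
        if isinstance(e, Cluster):
            positions = set()
            for member in e.members:
                positions |= set(member.positions)
        else:
            positions = e.positions
        densities.append(_positions_density(positions, grid))
    return CollectionStatistics(
        clusteredness=1.0 / mean_dist,
        density=float(np.mean(densities)) / mean_dist,
    )


def silhouette_index(clusters: list[Cluster]) -> float | None:
    """Mean Silhouette value of all member regions, or ``None`` when undefined.

    Uses the centroid-distance pseudometric as the dissimilarity.  Undefined
    (``None``) for fewer than two clusters and when every cluster is a
    singleton; member regions of singleton clusters contribute 0.
    """
    if len(clusters) < 2:
        return None
    if all(len(c.members) < 2 for c in clusters):
        return None
    regions = []
    labels = []
    for li, c in enumerate(clusters):
        for member in c.members:
            regions.append(member)
            labels.append(li)
    cents = np.array([r.centroid for r in regions])
    diff = cents[:, None, :] - cents[None, :, :]
    dmat = np.hypot(diff[..., 0], diff[..., 1])
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(dmat, np.array(labels), metric="precomputed"))
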