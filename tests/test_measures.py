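"""Spatial measures: formulas, geometry oracles and invariants."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_point_region, make_square_region
from stmc.geometry import (
    convex_hull_vertices,
    min_enclosing_circle,
    min_enclosing_rectangle_area,
    min_enclosing_triangle,
)
from stmc.measures import (
    CollectionStatistics,
    SpaceGeometry,
    angle_degrees,
    cluster_measures,
    collection_statistics,
    region_measures,
    shape_measure,
    shape_measures,
    silhouette_index,
)
from stmc.patterns import Cluster, Region, centroid_distance


# --- independent geometry oracles ------------------------------------------

def shoelace(vertices) -> float:
    v = np.asarray(vertices, float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def edge_walk_perimeter(vertices) -> float:
    v = np.asarray(vertices, float)
    return float(sum(math.dist(v[i], v[(i + 1) % len(v)]) for i in range(len(v))))


def calipers_rectangle_area(points) -> float:
    """Rotating-calipers oracle: min over hull-edge directions of the bbox."""
    hull = convex_hull_vertices(points)
    best = math.inf
    for i in range(len(hull)):
        edge = hull[(i + 1) % len(hull)] - hull[i]
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        u = edge / norm
        w = np.array([-u[1], u[0]])
        pu = hull @ u
        pw = hull @ w
        best = min(best, (pu.max() - pu.min()) * (pw.max() - pw.min()))
    return best


def brute_force_circle(points) -> float:
    """Smallest enclosing circle radius by pair/triple enumeration."""
    pts = [tuple(p) for p in np.asarray(points, float).reshape(-1, 2)]

    def covers(cx, cy, r):
        return all(math.hypot(x - cx, y - cy) <= r + 1e-9 for x, y in pts)

    best = math.inf
    if len(pts) == 1:
        return 0.0
    for (x1, y1), (x2, y2) in combinations(pts, 2):
        cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
        r = math.hypot(x1 - cx, y1 - cy)
        if r < best and covers(cx, cy, r):
            best = r
    for (x1, y1), (x2, y2), (x3, y3) in combinations(pts, 3):
        d = 2 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
        if abs(d) < 1e-12:
            continue
        ux = ((x1 ** 2 + y1 ** 2) * (y2 - y3) + (x2 ** 2 + y2 ** 2) * (y3 - y1)
              + (x3 ** 2 + y3 ** 2) * (y1 - y2)) / d
        uy = ((x1 ** 2 + y1 ** 2) * (x3 - x2) + (x2 ** 2 + y2 ** 2) * (x1 - x3)
              + (x3 ** 2 + y3 ** 2) * (x2 - x1)) / d
        r = math.hypot(x1 - ux, y1 - uy)
        if r < best and covers(ux, uy, r):
            best = r
    return best


def support_angle_triangle_area(points, n_grid: int = 90) -> float:
    """Numeric oracle for the minimum enclosing triangle.

    A triangle tangent to the hull is the intersection of three support
    half-planes; scan support-normal angle triples on a coarse grid and
    polish the best with Nelder-Mead.
    """
    from scipy.optimize import minimize

    hull = convex_hull_vertices(points)

    def support(phi):
        d = np.array([math.cos(phi), math.sin(phi)])
        return d, float((hull @ d).max())

    def area(angles):
        # the three outward normals must positively span the plane, else the
        # intersection of the support half-planes is unbounded
        ordered = np.sort(np.mod(angles, 2 * math.pi))
        gaps = np.diff(np.concatenate([ordered, [ordered[0] + 2 * math.pi]]))
        if gaps.max() >= math.pi - 1e-12:
            return math.inf
        lines = [support(phi) for phi in angles]
        verts = []
        for (d1, h1), (d2, h2) in combinations(lines, 2):
            det = d1[0] * d2[1] - d1[1] * d2[0]
            if abs(det) < 1e-12:
                return math.inf
            verts.append(np.array([(h1 * d2[1] - h2 * d1[1]) / det,
                                   (d1[0] * h2 - d2[0] * h1) / det]))
        a, b, c = verts
        return 0.5 * abs(float((b - a)[0] * (c - a)[1] - (b - a)[1] * (c - a)[0]))

    grid = np.linspace(0, 2 * math.pi, n_grid, endpoint=False)
    candidates = []
    for i in range(n_grid):
        for j in range(i + 1, n_grid):
            for k in range(j + 1, n_grid):
                angles = (grid[i], grid[j], grid[k])
                candidates.append((area(angles), angles))
    candidates.sort(key=lambda t: t[0])
    best = candidates[0][0]
    for start_area, start in candidates[:8]:
        res = minimize(area, start, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 5000})
        best = min(best, float(res.fun))
    return best


# --- clusteredness and region measures --------------------------------------

UNIT_SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]


class TestRegionMeasures:
    def test_hole_free_region_clusteredness_one(self, geom_101):
        region = make_square_region(10, 10, 5)
        grid = np.ones((101, 101))
        assert region_measures(region, grid, geom_101).clusteredness == 1.0

    def test_clusteredness_with_hole(self, geom_101):
        # outer polygon of area 120 containing one hole of area 20:
        # net area 100, clusteredness 100 / (100 + 20)
        outer = np.array([(0, 0), (12, 0), (12, 10), (0, 10)], float)
        hole = np.array([(2, 2), (7, 2), (7, 6), (2, 6)], float)
        region = Region(outer_contour=outer, holes=[hole],
                        positions=frozenset([(0, 0)]))
        m = region_measures(region, np.ones((101, 101)), geom_101)
        assert m.area == pytest.approx(100.0)
        assert m.clusteredness == pytest.approx(100.0 / 120.0)

    def test_density_is_mean_grid_value(self, geom_101):
        region = make_square_region(0, 0, 2)
        grid = np.zeros((101, 101))
        grid[0, 0], grid[0, 1], grid[1, 0], grid[1, 1] = 1, 2, 3, 6
        assert region_measures(region, grid, geom_101).density == pytest.approx(3.0)

    def test_centred_square_area_perimeter_distance(self):
        geom = SpaceGeometry(101, 101)
        region = make_square_region(46, 46, 10)  # covers the origin (50, 50)
        m = region_measures(region, np.ones((101, 101)), geom)
        assert m.distanceFromOrigin == 0.0
        assert m.area == pytest.approx(shoelace(region.outer_contour))
        assert m.perimeter == pytest.approx(
            edge_walk_perimeter(region.outer_contour))

    def test_perimeter_ignores_holes(self, geom_101):
        outer = np.array([(0, 0), (12, 0), (12, 10), (0, 10)], float)
        hole = np.array([(2, 2), (7, 2), (7, 6), (2, 6)], float)
        with_hole = Region(outer_contour=outer, holes=[hole],
                           positions=frozenset([(0, 0)]))
        without = Region(outer_contour=outer, positions=frozenset([(0, 0)]))
        grid = np.ones((101, 101))
        assert region_measures(with_hole, grid, geom_101).perimeter \
            == region_measures(without, grid, geom_101).perimeter

    def test_clusteredness_decreases_with_hole_area(self, geom_101):
        outer = np.array([(0, 0), (20, 0), (20, 20), (0, 20)], float)
        grid = np.ones((101, 101))
        previous = 1.1
        for side in (2, 5, 8, 11):
            hole = np.array([(1, 1), (1 + side, 1), (1 + side, 1 + side),
                             (1, 1 + side)], float)
            region = Region(outer_contour=outer, holes=[hole],
                            positions=frozenset([(0, 0)]))
            value = region_measures(region, grid, geom_101).clusteredness
            assert value < previous
            previous = value


class TestShapeMeasures:
    def test_triangle_is_its_own_enclosure(self):
        assert shape_measure([(0, 0), (4, 0), (0, 3)], "triangular") \
            == pytest.approx(1.0, abs=1e-9)

    def test_unit_square_circular_measure(self):
        assert shape_measure(UNIT_SQUARE, "circular") \
            == pytest.approx(2 / math.pi, abs=1e-9)

    def test_unit_square_rectangular_measure(self):
        assert shape_measure(UNIT_SQUARE, "rectangular") \
            == pytest.approx(1.0, abs=1e-9)

    def test_regular_64gon_rectangular_limit(self):
        theta = np.linspace(0, 2 * math.pi, 65)[:-1]
        polygon = np.c_[np.cos(theta), np.sin(theta)]
        assert shape_measure(polygon, "rectangular") \
            == pytest.approx(math.pi / 4, abs=0.01)

    def test_degenerate_polygon_measures_zero(self):
        for shape in ("triangular", "rectangular", "circular"):
            assert shape_measure([(0, 0), (5, 5)], shape) == 0.0

    def test_min_triangle_against_support_angle_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(4):
            pts = rng.uniform(0, 10, size=(8, 2))
            area, tri = min_enclosing_triangle(pts)
            oracle = support_angle_triangle_area(pts, n_grid=60)
            assert area == pytest.approx(oracle, rel=1e-6)
            hull = convex_hull_vertices(pts)
            # the returned triangle indeed encloses the hull
            for p in hull:
                s = []
                for i in range(3):
                    e = tri[(i + 1) % 3] - tri[i]
                    w = p - tri[i]
                    s.append(float(e[0] * w[1] - e[1] * w[0]))
                assert all(v >= -1e-7 for v in s) or all(v <= 1e-7 for v in s)

    def test_min_triangle_of_square_is_double_area(self):
        area, _ = min_enclosing_triangle(UNIT_SQUARE)
        assert area == pytest.approx(2.0, abs=1e-9)

    def test_min_rectangle_against_calipers_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            pts = rng.uniform(0, 10, size=(10, 2))
            assert min_enclosing_rectangle_area(pts) \
                == pytest.approx(calipers_rectangle_area(pts), rel=1e-9)

    def test_min_circle_against_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = rng.uniform(0, 10, size=(9, 2))
            radius, _ = min_enclosing_circle(pts)
            assert radius == pytest.approx(brute_force_circle(pts), rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000), st.floats(0.1, 50.0))
    def test_scale_invariance(self, seed, factor):
        rng = np.random.default_rng(seed)
        polygon = convex_hull_vertices(rng.uniform(0, 10, size=(8, 2)))
        tri, rect, circ, _ = shape_measures(polygon)
        tri2, rect2, circ2, _ = shape_measures(polygon * factor)
        assert tri2 == pytest.approx(tri, rel=1e-6)
        assert rect2 == pytest.approx(rect, rel=1e-6)
        assert circ2 == pytest.approx(circ, rel=1e-6)
        assert shoelace(polygon * factor) \
            == pytest.approx(shoelace(polygon) * factor ** 2, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_measures_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        polygon = convex_hull_vertices(rng.uniform(0, 20, size=(7, 2)))
        tri, rect, circ, _ = shape_measures(polygon)
        assert 0.0 <= tri <= 1.0
        assert 0.0 <= rect <= 1.0
        assert 0.0 <= circ <= 1.0

    def test_shape_tie_order(self):
        # a triangle ties nothing: triangular wins outright
        assert shape_measures([(0, 0), (4, 0), (0, 3)])[3] == "triangular"
        assert shape_measures(UNIT_SQUARE)[3] == "rectangular"


class TestAngle:
    def test_perpendicular_segment_oracle(self):
        # hull: vertical segment of half-length h at distance D from origin
        geom = SpaceGeometry(rows=1, cols=1)  # origin (0, 0)
        h, dist = 3.0, 4.0
        polygon = [(dist, -h), (dist, h), (dist, 0.0)]
        expected = math.degrees(2 * math.atan(h / dist))
        assert angle_degrees(polygon, geom) == pytest.approx(expected, abs=1e-9)

    def test_origin_inside_hull_gives_360(self):
        geom = SpaceGeometry(rows=1, cols=1)
        assert angle_degrees([(-1, -1), (1, -1), (1, 1), (-1, 1)], geom) == 360.0

    def test_point_like_hull_gives_zero(self):
        geom = SpaceGeometry(rows=1, cols=1)
        assert angle_degrees([(3.0, 4.0)], geom) == 0.0

    def test_wide_square_subtends_larger_angle_than_far_one(self, geom_101):
        near = make_square_region(55, 48, 6).outer_contour
        far = make_square_region(80, 48, 6).outer_contour
        assert angle_degrees(near, geom_101) > angle_degrees(far, geom_101)


class TestClusterMeasures:
    def test_single_region_cluster_clusteredness_one(self, geom_101):
        cluster = Cluster(members=[make_square_region(10, 10, 3)])
        grid = np.ones((101, 101))
        assert cluster_measures(cluster, grid, geom_101).clusteredness == 1.0

    def test_two_member_inverse_mean_distance(self, geom_101):
        cluster = Cluster(members=[make_point_region(0, 0),
                                   make_point_region(0, 4)])
        m = cluster_measures(cluster, np.ones((101, 101)), geom_101)
        assert m.clusteredness == pytest.approx(0.25)

    def test_collinear_members_degenerate_hull(self, geom_101):
        cluster = Cluster(members=[make_point_region(0, 0),
                                   make_point_region(10, 0),
                                   make_point_region(20, 0)])
        m = cluster_measures(cluster, np.ones((101, 101)), geom_101)
        assert m.area == 0.0
        assert m.perimeter == pytest.approx(2 * 20.0)

    def test_cluster_area_is_hull_area(self, geom_101):
        cluster = Cluster(members=[make_square_region(0, 0, 3),
                                   make_square_region(10, 0, 3),
                                   make_square_region(0, 10, 3)])
        m = cluster_measures(cluster, np.ones((101, 101)), geom_101)
        hull = convex_hull_vertices(
            np.vstack([r.outer_contour for r in cluster.members]))
        assert m.area == pytest.approx(shoelace(hull))

    def test_cluster_density_pools_member_positions(self, geom_101):
        grid = np.zeros((101, 101))
        grid[0, 0], grid[0, 4] = 2.0, 6.0
        cluster = Cluster(members=[make_point_region(0, 0),
                                   make_point_region(4, 0)])
        assert cluster_measures(cluster, grid, geom_101).density \
            == pytest.approx(4.0)


class TestCollectionStatistics:
    def test_two_entities_five_apart(self, geom_101):
        entities = [make_point_region(0, 0), make_point_region(3, 4)]
        stats = collection_statistics(entities, np.ones((101, 101)), geom_101)
        assert stats.clusteredness == pytest.approx(0.2)

    def test_single_entity_convention(self, geom_101):
        stats = collection_statistics([make_point_region(5, 5)],
                                      np.ones((101, 101)), geom_101)
        assert stats == CollectionStatistics(clusteredness=1.0, density=1.0)

    def test_empty_collection(self, geom_101):
        stats = collection_statistics([], np.ones((101, 101)), geom_101)
        assert stats.clusteredness == 1.0
        assert stats.density == 0.0

    def test_matches_brute_force_pairwise_mean(self, geom_101,
                                               random_region_factory):
        rng = np.random.default_rng(9)
        entities = random_region_factory(rng, 5)
        grid = np.ones((101, 101))
        stats = collection_statistics(entities, grid, geom_101)
        pairwise = [centroid_distance(a, b)
                    for a, b in combinations(entities, 2)]
        expected = 1.0 / (sum(pairwise) / len(pairwise))
        assert stats.clusteredness == pytest.approx(expected, abs=1e-9)
        assert stats.density == pytest.approx(expected, abs=1e-9)  # unit grid


def brute_force_silhouette(clusters):
    """Textbook Silhouette on region centroids (0 for singleton members)."""
    entries = [(li, m) for li, c in enumerate(clusters) for m in c.members]
    values = []
    for li, m in entries:
        own = [x for lj, x in entries if lj == li and x is not m]
        if not own:
            values.append(0.0)
            continue
        a = sum(centroid_distance(m, x) for x in own) / len(own)
        b = math.inf
        for lj in range(len(clusters)):
            if lj == li:
                continue
            other = [x for lk, x in entries if lk == lj]
            b = min(b, sum(centroid_distance(m, x) for x in other) / len(other))
        values.append((b - a) / max(a, b))
    return sum(values) / len(values)


class TestSilhouette:
    def test_two_tight_far_clusters(self):
        c1 = Cluster(members=[make_point_region(0, 0), make_point_region(1, 0),
                              make_point_region(0, 1)])
        c2 = Cluster(members=[make_point_region(100, 100),
                              make_point_region(101, 100),
                              make_point_region(100, 101)])
        value = silhouette_index([c1, c2])
        assert value > 0.9
        assert value == pytest.approx(brute_force_silhouette([c1, c2]), abs=1e-9)

    def test_matches_brute_force_on_random_inputs(self, random_region_factory):
        rng = np.random.default_rng(21)
        for _ in range(10):
            regions = random_region_factory(rng, 12, span=30)
            clusters = [Cluster(members=regions[:4]),
                        Cluster(members=regions[4:7]),
                        Cluster(members=regions[7:])]
            value = silhouette_index(clusters)
            assert -1.0 <= value <= 1.0
            assert value == pytest.approx(
                brute_force_silhouette(clusters), abs=1e-9)

    def test_undefined_cases_return_none(self):
        single = [Cluster(members=[make_point_region(0, 0),
                                   make_point_region(1, 1)])]
        assert silhouette_index(single) is None
        singletons = [Cluster(members=[make_point_region(0, 0)]),
                      Cluster(members=[make_point_region(5, 5)])]
        assert silhouette_index(singletons) is None
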