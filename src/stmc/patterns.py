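"""Detection of spatial patterns (regions) and clusters of patterns.

A pseudo-3D state grid -- an ``m x n`` matrix of non-negative reals, one per
spatial state variable and timepoint -- is normalised to a grayscale image and
passed through a parameterised segmentation pipeline: brightness/contrast
adjustment, morphological closing, Gaussian blur, binary thresholding,
two-level contour extraction (outer boundaries and holes) and polygonal
approximation.  Surviving connected components above the size threshold are
*regions*.  Groups of regions whose centroids are mutually close are found
with a density-based clustering algorithm (DBSCAN) made order-independent by
a deterministic border-point assignment rule.

Coordinate convention: grids are row-major with position ``(row, col)``;
polygons use ``(x=col, y=row)`` with y growing downward.  Contours trace
pixel centres and ``|positions|`` counts pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Point, Polygon

from .errors import ParameterError

_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


def as_state_grid(values) -> np.ndarray:
    """Validate and return *values* as an ``m x n`` float array of non-negative reals."""
    grid = np.asarray(values, dtype=float)
    if grid.ndim != 2 or grid.size == 0:
        raise ParameterError("state grid must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(grid)) or np.any(grid < 0):
        raise ParameterError("state grid entries must be finite and non-negative")
    return grid


def read_grid_csv(path) -> np.ndarray:
    """Read a state grid from a headerless comma-separated numeric matrix."""
    return as_state_grid(np.loadtxt(str(path), delimiter=",", ndmin=2))


def read_grid_png(path) -> np.ndarray:
    """Read a grayscale PNG as a state grid of intensities."""
    from PIL import Image

    with Image.open(str(path)) as img:
        return as_state_grid(np.asarray(img.convert("L"), dtype=float))


def grid_to_grayscale(grid, normalization_max="auto") -> np.ndarray:
    """Convert a state grid to a grayscale image (integers in [0, 255]).

    ``intensity = round(255 * min(1, value / normalization_max))`` with
    round-half-up; ``"auto"`` uses the grid maximum (an all-zero grid maps to
    the all-zero image).
    """
    grid = as_state_grid(grid)
    if normalization_max == "auto":
        normalization_max = float(grid.max())
        if normalization_max <= 0:
            return np.zeros(grid.shape, dtype=np.uint8)
    normalization_max = float(normalization_max)
    if normalization_max <= 0:
        raise ParameterError("normalization_max must be positive")
    scaled = 255.0 * np.minimum(1.0, grid / normalization_max)
    return np.floor(scaled + 0.5).astype(np.uint8)


@dataclass
class RegionDetectionConfig:
    """Parameters of the region-detection pipeline.

    alpha/beta are the contrast gain and brightness offset; the threshold is
    on the 0-255 intensity scale (the raw-value threshold divided by the
    normalisation maximum and rescaled by 255).  ``epsilon_size`` is the
    strict minimum region cardinality in pixels.  ``point_mode`` bypasses
    closing/blur/contours and emits one single-pixel region per position at
    or above the threshold (lightweight cell detector).
    """

    alpha: float = 1.0
    beta: float = 0.0
    morph_close_iterations: int = 0
    blur_kernel_size: int = 1
    blur_std_dev: float = 0.0
    threshold_value: int = 127
    epsilon_size: float = 0.0
    approximation_level: float = 0.0
    point_mode: bool = False

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ParameterError("alpha must be > 0")
        if self.morph_close_iterations < 0:
            raise ParameterError("morph_close_iterations must be >= 0")
        if self.blur_kernel_size < 1 or self.blur_kernel_size % 2 == 0:
            raise ParameterError("blur_kernel_size must be an odd positive integer")
        if self.blur_std_dev < 0:
            raise ParameterError("blur_std_dev must be >= 0")
        if not (0 <= self.threshold_value <= 255):
            raise ParameterError("threshold_value must lie in [0, 255]")
        if self.epsilon_size < 0 or self.approximation_level < 0:
            raise ParameterError("epsilon_size and approximation_level must be >= 0")


def _polygon_area_centroid(vertices: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Shoelace area and moments-based centroid of a closed polygon.

    Falls back to the vertex mean when the polygon is degenerate (area 0).
    """
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0, tuple(v.mean(axis=0))
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    signed = 0.5 * cross.sum()
    if abs(signed) < 1e-12:
        return 0.0, tuple(v.mean(axis=0))
    cx = ((x + xn) * cross).sum() / (6.0 * signed)
    cy = ((y + yn) * cross).sum() / (6.0 * signed)
    return abs(signed), (cx, cy)


@dataclass
class Region:
    """A detected spatial pattern: polygon-with-holes over grid coordinates."""

    outer_contour: np.ndarray  # (k, 2) array of (x, y) pixel-centre vertices
    holes: list[np.ndarray] = field(default_factory=list)
    positions: frozenset = frozenset()  # set of (row, col) pixels covered

    def __post_init__(self):
        self.outer_contour = np.asarray(self.outer_contour, dtype=float).reshape(-1, 2)
        if len(self.outer_contour) > 0:
            area, centroid = _polygon_area_centroid(self.outer_contour)
        else:  # no boundary recorded: fall back to the pixel set
            area = 0.0
            pts = np.array([(c, r) for r, c in sorted(self.positions)], dtype=float)
            centroid = tuple(pts.mean(axis=0))
        self._outer_area = area
        self._centroid = centroid

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) centroid from polygon moments (pixel mean when degenerate)."""
        return self._centroid

    @property
    def outer_area(self) -> float:
        return self._outer_area

    def outer_polygon(self):
        """The outer contour as a valid shapely geometry (for distances)."""
        if len(self.outer_contour) >= 3:
            poly = Polygon(self.outer_contour)
            if not poly.is_valid:
                poly = poly.buffer(0)
            if not poly.is_empty:
                return poly
        if self.positions:
            return MultiPoint([(c, r) for r, c in sorted(self.positions)])
        return Point(self._centroid)


@dataclass
class Cluster:
    """A group of regions found by density-based clustering."""

    members: list[Region]

    @property
    def centroid(self) -> tuple[float, float]:
        """Centroid of the convex hull of all member regions."""
        pts = np.vstack([m.outer_contour for m in self.members])
        hull = MultiPoint(pts).convex_hull
        if hull.geom_type == "Polygon":
            c = hull.centroid
            return (c.x, c.y)
        c = hull.centroid  # point or segment hull
        return (c.x, c.y)


def centroid_distance(a, b) -> float:
    """Euclidean distance between the centroids of two spatial entities.

    This is the pseudometric used both for clustering regions and for
    group-level clusteredness: entities at the same location have distance 0
    even when they differ.
    """
    (xa, ya), (xb, yb) = a.centroid, b.centroid
    return float(np.hypot(xb - xa, yb - ya))


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a connected pixel set along pixel centres.

    Moore neighbourhood tracing with the modified Jacob stopping criterion;
    returns an array of (row, col) boundary pixels in traversal order.
    """
    pts = np.argwhere(mask)
    start = tuple(pts[0])  # topmost, then leftmost
    if len(pts) == 1:
        return pts.astype(int)
    cur = start
    backtrack = (start[0], start[1] - 1)  # west of start is background
    # The (pixel, backtrack) dynamics are deterministic, so the walk is
    # eventually periodic; the boundary cycle is the orbit from the first
    # repeated state.
    seen: dict = {}
    sequence: list = []
    max_steps = 8 * int(mask.sum()) + 16
    for _ in range(max_steps):
        state = (cur, backtrack)
        if state in seen:
            cycle = [pixel for pixel, _ in sequence[seen[state]:]]
            return np.array(cycle, dtype=int)
        seen[state] = len(sequence)
        sequence.append(state)
        bi = _MOORE.index((backtrack[0] - cur[0], backtrack[1] - cur[1]))
        nxt = prev_checked = None
        for k in range(1, 9):
            d = _MOORE[(bi + k) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if (0 <= cand[0] < mask.shape[0] and 0 <= cand[1] < mask.shape[1]
                    and mask[cand]):
                nxt = cand
                pd = _MOORE[(bi + k - 1) % 8]
                prev_checked = (cur[0] + pd[0], cur[1] + pd[1])
                break
        if nxt is None:  # isolated pixel (cannot happen for len > 1)
            break
        cur, backtrack = nxt, prev_checked
    return np.array([pixel for pixel, _ in sequence], dtype=int)


def _approximate(contour_xy: np.ndarray, tolerance: float) -> np.ndarray:
    if tolerance <= 0 or len(contour_xy) < 3:
        return contour_xy
    from skimage.measure import approximate_polygon

    closed = np.vstack([contour_xy, contour_xy[:1]])
    approx = approximate_polygon(closed, tolerance)
    if len(approx) > 1 and np.array_equal(approx[0], approx[-1]):
        approx = approx[:-1]
    return approx


def _gaussian_kernel_1d(ksize: int, sigma: float) -> np.ndarray:
    if sigma <= 0:
        # kernel-size-derived default of the classical image pipelines
        sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
    centre = (ksize - 1) / 2.0
    i = np.arange(ksize)
    k = np.exp(-((i - centre) ** 2) / (2.0 * sigma * sigma))
    return k / k.sum()


def _preprocess(image: np.ndarray, config: RegionDetectionConfig) -> np.ndarray:
    img = np.floor(config.alpha * image.astype(float) + config.beta + 0.5)
    img = np.clip(img, 0, 255)
    if config.morph_close_iterations > 0:
        n = config.morph_close_iterations
        size = (3, 3)
        for _ in range(n):
            img = ndimage.grey_dilation(img, size=size, mode="nearest")
        for _ in range(n):
            img = ndimage.grey_erosion(img, size=size, mode="nearest")
    if config.blur_kernel_size > 1:
        k = _gaussian_kernel_1d(config.blur_kernel_size, config.blur_std_dev)
        img = ndimage.convolve1d(img, k, axis=0, mode="mirror")
        img = ndimage.convolve1d(img, k, axis=1, mode="mirror")
        img = np.floor(img + 0.5)
    return np.clip(img, 0, 255)


def detect_regions(image, config: RegionDetectionConfig) -> list[Region]:
    """Run the full region-detection pipeline on a grayscale image.

    Returns regions with ``|positions| > epsilon_size`` (strict), sorted by
    (centroidY, centroidX) for determinism.
    """
    config.validate()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ParameterError("image must be 2-D grayscale")

    if config.point_mode:
        return _detect_point_regions(image, config)

    img = _preprocess(image, config)
    foreground = img > config.threshold_value
    labels, n_components = ndimage.label(foreground, structure=np.ones((3, 3), bool))

    regions: list[Region] = []
    for lbl in range(1, n_components + 1):
        mask = labels == lbl
        n_pixels = int(mask.sum())
        if n_pixels <= config.epsilon_size:
            continue
        outer_rc = _moore_trace(mask)
        outer_xy = outer_rc[:, ::-1].astype(float)  # (row, col) -> (x, y)
        outer_xy = _approximate(outer_xy, config.approximation_level)

        filled = ndimage.binary_fill_holes(mask)
        holes_mask = filled & ~mask
        holes: list[np.ndarray] = []
        if holes_mask.any():
            hole_labels, n_holes = ndimage.label(holes_mask)  # 4-connected holes
            for h in range(1, n_holes + 1):
                hole_rc = _moore_trace(hole_labels == h)
                hole_xy = hole_rc[:, ::-1].astype(float)
                holes.append(_approximate(hole_xy, config.approximation_level))

        positions = frozenset(map(tuple, np.argwhere(mask)))
        regions.append(Region(outer_contour=outer_xy, holes=holes,
                              positions=positions))

    regions.sort(key=lambda r: (r.centroid[1], r.centroid[0]))
    return regions


def _detect_point_regions(image, config) -> list[Region]:
    rows, cols = np.nonzero(np.asarray(image) >= config.threshold_value)
    regions = [
        Region(outer_contour=np.array([[c, r]], dtype=float),
               positions=frozenset([(int(r), int(c))]))
        for r, c in zip(rows.tolist(), cols.tolist())
    ]
    regions.sort(key=lambda r: (r.centroid[1], r.centroid[0]))
    return regions


@dataclass
class ClusterDetectionConfig:
    """Parameters of the cluster-detection (DBSCAN) step.

    ``epsilon_distance`` is the neighbourhood radius on centroid distances;
    ``epsilon_size`` the strict minimum member count of a reported cluster;
    ``min_neighbours`` the DBSCAN core-point condition (neighbourhood size
    including the point itself).
    """

    epsilon_distance: float = 1.5
    epsilon_size: float = 0.0
    min_neighbours: int = 2

    def validate(self) -> None:
        if self.epsilon_distance < 0 or self.epsilon_size < 0:
            raise ParameterError("epsilon_distance and epsilon_size must be >= 0")
        if self.min_neighbours < 1:
            raise ParameterError("min_neighbours must be >= 1")


def detect_clusters(regions: list[Region],
                    config: ClusterDetectionConfig) -> list[Cluster]:
    """Group regions into clusters by centroid distance (order-independent DBSCAN).

    Core regions (at least ``min_neighbours`` regions, themselves included,
    within ``epsilon_distance``) are linked into clusters through chains of
    mutually close cores; border regions within reach of several clusters are
    assigned to the cluster whose nearest core is closest, ties broken by the
    lowest cluster label after canonical (centroidY, centroidX) sorting of
    the input.  Clusters with ``|C| <= epsilon_size`` are discarded.  The
    output is invariant under any permutation of the input list.
    """
    config.validate()
    if not regions:
        return []
    order = sorted(range(len(regions)),
                   key=lambda i: (regions[i].centroid[1], regions[i].centroid[0]))
    regs = [regions[i] for i in order]
    n = len(regs)
    cents = np.array([r.centroid for r in regs])
    d = np.hypot(cents[:, 0:1] - cents[None, :, 0], cents[:, 1:2] - cents[None, :, 1])
    adj = d <= config.epsilon_distance
    core = adj.sum(axis=1) >= config.min_neighbours

    labels = np.full(n, -1, dtype=int)
    next_label = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        # flood over the core graph in canonical order
        labels[i] = next_label
        stack = [i]
        while stack:
            j = stack.pop()
            for k in np.nonzero(adj[j] & core)[0]:
                if labels[k] == -1:
                    labels[k] = next_label
                    stack.append(k)
        next_label += 1

    # deterministic border assignment: nearest core, ties by lowest label
    core_idx = np.nonzero(core)[0]
    for i in range(n):
        if core[i] or labels[i] != -1:
            continue
        reachable = core_idx[adj[i, core_idx]]
        if reachable.size == 0:
            continue  # noise
        dist = d[i, reachable]
        best = dist.min()
        candidates = reachable[np.isclose(dist, best, rtol=0, atol=1e-12)]
        labels[i] = int(min(labels[c] for c in candidates))

    clusters = []
    for lbl in range(next_label):
        members = [regs[i] for i in np.nonzero(labels == lbl)[0]]
        if len(members) > config.epsilon_size:
            clusters.append(Cluster(members=members))
    return clusters
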