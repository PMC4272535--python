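"""Synthetic pseudo-3D simulation traces for the two benchmark scenarios.

Neither original simulator (a stochastic Petri-net colony model; a Cellular
Potts chemotaxis model) is reimplemented here; the generators reproduce only
the qualitative spatio-temporal phenomenology the example specifications
test -- angular sector-like patches of switched cells in a radially growing
colony, and the chemotactic aggregation of lattice cells toward a static
2-D Gaussian attractant -- which is all the checker consumes.  Both are
bit-reproducible under a fixed seed.

Also provides exact raster fixtures (squares, discs, triangles) for
geometry oracles, and the translation of generated traces into STML
experiments through the detection and measure pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .measures import SpaceGeometry, cluster_measures, region_measures, silhouette_index
from .patterns import (
    ClusterDetectionConfig,
    RegionDetectionConfig,
    detect_clusters,
    detect_regions,
    grid_to_grayscale,
)
from .stml import Experiment, NumericStateVariableRecord, Timepoint

_NEIGHBOURS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class ColonyGeneratorConfig:
    """Radially growing two-type colony with stochastic type switching.

    The colony starts from a single wild-type cell at the grid centre and
    colonises outward at ``growth_rate_per_step`` lattice units per
    timepoint.  A newly colonised position inherits the majority type of
    its occupied neighbours (ties broken at random) and switches type with
    ``switch_probability`` per division; switched lineages spread as
    angular sectors whose width grows with radius.
    ``n_sector_seeds_expected`` optionally caps the number of
    wild-type-to-mutant switch events (None = unlimited).
    """

    grid_size: tuple[int, int] = (101, 101)
    n_timepoints: int = 40
    switch_probability: float = 0.05
    growth_rate_per_step: float = 1.25
    n_sector_seeds_expected: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.switch_probability <= 1.0):
            raise ParameterError("switch_probability must lie in [0, 1]")
        if self.n_timepoints < 1 or self.growth_rate_per_step <= 0:
            raise ParameterError("n_timepoints >= 1 and growth rate > 0 required")


def generate_colony_trace(cfg: ColonyGeneratorConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Simulate colony growth; returns per-timepoint (wildtype, mutant) grids."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_size
    centre = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    types = np.full((rows, cols), -1, dtype=np.int8)  # -1 empty, 0 wt, 1 mutant
    types[int(centre[0]), int(centre[1])] = 0
    seeds_used = 0

    rr, cc = np.mgrid[0:rows, 0:cols]
    radius2 = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2

    trace = []
    for t in range(cfg.n_timepoints):
        r = cfg.growth_rate_per_step * t
        # colonise in waves so every new cell touches an occupied one
        while True:
            occupied = types >= 0
            candidate = (~occupied) & (radius2 <= r * r)
            if not candidate.any():
                break
            # adjacency to an occupied cell
            padded = np.pad(occupied, 1)
            touch = np.zeros_like(occupied)
            for dr, dc in _NEIGHBOURS8:
                touch |= padded[1 + dr:1 + dr + rows, 1 + dc:1 + dc + cols]
            frontier = np.argwhere(candidate & touch)
            if len(frontier) == 0:
                break
            new_types = {}
            for pr, pc in frontier:  # row-major deterministic order
                votes = [types[pr + dr, pc + dc]
                         for dr, dc in _NEIGHBOURS8
                         if 0 <= pr + dr < rows and 0 <= pc + dc < cols
                         and types[pr + dr, pc + dc] >= 0]
                n_mut = sum(votes)
                if 2 * n_mut > len(votes):
                    inherited = 1
                elif 2 * n_mut < len(votes):
                    inherited = 0
                else:
                    inherited = int(rng.integers(0, 2))
                if rng.random() < cfg.switch_probability:
                    if inherited == 0:
                        if (cfg.n_sector_seeds_expected is None
                                or seeds_used < cfg.n_sector_seeds_expected):
                            inherited = 1
                            seeds_used += 1
                    else:
                        inherited = 0
                new_types[(pr, pc)] = inherited
            for (pr, pc), ty in new_types.items():
                types[pr, pc] = ty
        trace.append(((types == 0).astype(float), (types == 1).astype(float)))
    return trace


@dataclass
class ChemotaxisGeneratorConfig:
    """Lattice random walkers biased toward a static 2-D Gaussian attractant.

    ``n_cells`` cells start at distinct random positions of the lattice
    (1% occupancy at the defaults).  Per step each cell moves greedily
    uphill on the attractant with probability ``attraction_strength`` and
    performs an unbiased step otherwise; several cells may share a position
    (pileup) up to the soft volume-exclusion capacity ``max_pileup``.
    ``n_timepoints`` recorded states cover ``n_timepoints - 1`` movement
    steps.
    """

    lattice_size: tuple[int, int] = (100, 100)
    n_cells: int = 100
    mu_x: float = 50.0
    mu_y: float = 50.0
    sigma_x: float = 10.0
    sigma_y: float = 10.0
    attraction_strength: float = 1.0
    n_timepoints: int = 201
    max_pileup: int = 3
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.lattice_size
        if self.n_cells < 1 or self.n_cells > rows * cols // 2:
            raise ParameterError(
                "n_cells must be at least 1 and at most half the lattice capacity"
            )
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ParameterError("attractant sigma must be > 0")
        if not (0.0 <= self.attraction_strength <= 1.0):
            raise ParameterError("attraction_strength must lie in [0, 1]")
        if self.n_timepoints < 1:
            raise ParameterError("n_timepoints must be >= 1")
        if self.max_pileup < 1:
            raise ParameterError("max_pileup must be >= 1")


def attractant_field(cfg: ChemotaxisGeneratorConfig) -> np.ndarray:
    """The static Gaussian attractant concentration grid."""
    rows, cols = cfg.lattice_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    return np.exp(-((cc - cfg.mu_x) ** 2 / (2 * cfg.sigma_x ** 2)
                    + (rr - cfg.mu_y) ** 2 / (2 * cfg.sigma_y ** 2)))


def generate_chemotaxis_trace(cfg: ChemotaxisGeneratorConfig
                              ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Simulate biased walkers; returns per-timepoint (cellCount, attractant) grids."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.lattice_size
    attractant = attractant_field(cfg)

    flat = rng.choice(rows * cols, size=cfg.n_cells, replace=False)
    positions = np.stack([flat // cols, flat % cols], axis=1)
    counts = np.zeros((rows, cols))
    np.add.at(counts, (positions[:, 0], positions[:, 1]), 1.0)

    trace = [(counts.copy(), attractant.copy())]
    for _ in range(cfg.n_timepoints - 1):
        for i in range(cfg.n_cells):
            pr, pc = positions[i]
            target = None
            if rng.random() < cfg.attraction_strength:
                # greedy uphill step (stay when already at a local maximum
                # or when all better neighbours are at capacity)
                best_val = attractant[pr, pc]
                for dr, dc in _NEIGHBOURS8:
                    nr, nc = pr + dr, pc + dc
                    if 0 <= nr < rows and 0 <= nc < cols \
                            and attractant[nr, nc] > best_val \
                            and counts[nr, nc] < cfg.max_pileup:
                        target, best_val = (nr, nc), attractant[nr, nc]
            else:
                valid = [(pr + dr, pc + dc) for dr, dc in _NEIGHBOURS8
                         if 0 <= pr + dr < rows and 0 <= pc + dc < cols
                         and counts[pr + dr, pc + dc] < cfg.max_pileup]
                if valid:
                    target = valid[rng.integers(0, len(valid))]
            if target is not None:
                counts[pr, pc] -= 1.0
                counts[target] += 1.0
                positions[i] = target
        trace.append((counts.copy(), attractant.copy()))
    return trace


def rasterize_shape(shape: str, *, grid_size: tuple[int, int],
                    side: int | None = None,
                    radius: float | None = None,
                    center: tuple[float, float] | None = None,
                    vertices=None) -> np.ndarray:
    """Exact binary raster of a basic shape (pixel membership by inequality).

    ``square`` needs ``side``; ``disc`` needs ``radius``; ``triangle`` needs
    ``vertices`` (three (x, y) points).  ``center`` defaults to the grid
    centre.  Raises when the shape does not fit in the grid.
    """
    rows, cols = grid_size
    grid = np.zeros((rows, cols))
    if center is None:
        center = ((cols - 1) / 2.0, (rows - 1) / 2.0)
    cx, cy = center
    if shape == "square":
        if side is None or side < 1:
            raise ParameterError("square needs a positive integer side")
        r0 = int(round(cy - (side - 1) / 2.0))
        c0 = int(round(cx - (side - 1) / 2.0))
        if r0 < 0 or c0 < 0 or r0 + side > rows or c0 + side > cols:
            raise ParameterError("square does not fit in the grid")
        grid[r0:r0 + side, c0:c0 + side] = 1.0
        return grid
    if shape == "disc":
        if radius is None or radius < 0:
            raise ParameterError("disc needs a non-negative radius")
        if cx - radius < 0 or cy - radius < 0 \
                or cx + radius > cols - 1 or cy + radius > rows - 1:
            raise ParameterError("disc does not fit in the grid")
        rr, cc = np.mgrid[0:rows, 0:cols]
        grid[(cc - cx) ** 2 + (rr - cy) ** 2 <= radius ** 2] = 1.0
        return grid
    if shape == "triangle":
        if vertices is None or len(vertices) != 3:
            raise ParameterError("triangle needs exactly three vertices")
        v = np.asarray(vertices, dtype=float)
        if v[:, 0].min() < 0 or v[:, 1].min() < 0 \
                or v[:, 0].max() > cols - 1 or v[:, 1].max() > rows - 1:
            raise ParameterError("triangle does not fit in the grid")
        rr, cc = np.mgrid[0:rows, 0:cols]
        inside = np.ones((rows, cols), dtype=bool)
        e1, e2 = v[1] - v[0], v[2] - v[0]
        area2 = float(e1[0] * e2[1] - e1[1] * e2[0])
        if area2 == 0.0:
            raise ParameterError("triangle vertices are collinear")
        orient = np.sign(area2)
        for a, b in ((v[0], v[1]), (v[1], v[2]), (v[2], v[0])):
            cross = (b[0] - a[0]) * (rr - a[1]) - (b[1] - a[1]) * (cc - a[0])
            inside &= orient * cross >= -1e-9
        grid[inside] = 1.0
        return grid
    raise ParameterError(f"unknown shape {shape!r}")


@dataclass
class TraceToStmlConfig:
    """How a generated trace is analysed into an STML experiment."""

    mode: str = "regions"  # regions | clusters | pointClusters
    detection: RegionDetectionConfig = field(default_factory=RegionDetectionConfig)
    clustering: ClusterDetectionConfig = field(default_factory=ClusterDetectionConfig)


def trace_to_stml(trace, config: TraceToStmlConfig) -> Experiment:
    """Analyse a generated trace into an STML experiment.

    ``regions`` mode treats each trace item as ``(wildtype, mutant)`` count
    grids and detects regions on the mutant fraction
    ``mutant / (wildtype + mutant)`` (0 at empty positions);
    ``pointClusters`` mode treats items as ``(cellCount, attractant)`` and
    clusters single-pixel cell detections; ``clusters`` mode runs the full
    region pipeline first and clusters the result.  Cluster modes record
    the Silhouette cluster-validity index as the numeric state variable
    ``avgClusterednessClusters`` whenever it is defined (at least two
    clusters, not all singletons).
    """
    if config.mode not in ("regions", "clusters", "pointClusters"):
        raise ParameterError(f"unknown mode {config.mode!r}")
    timepoints = []
    for t, item in enumerate(trace):
        first, second = item
        if config.mode == "regions":
            wildtype, mutant = np.asarray(first, float), np.asarray(second, float)
            total = wildtype + mutant
            with np.errstate(invalid="ignore"):
                grid = np.where(total > 0, mutant / np.maximum(total, 1e-300), 0.0)
        else:
            grid = np.asarray(first, float)
        geom = SpaceGeometry(rows=grid.shape[0], cols=grid.shape[1])
        image = grid_to_grayscale(grid, 1.0 if config.mode == "regions" else "auto")
        regions = detect_regions(image, config.detection)

        entities = []
        variables = []
        if config.mode == "regions":
            entities = [region_measures(r, grid, geom) for r in regions]
        else:
            clusters = detect_clusters(regions, config.clustering)
            entities = [cluster_measures(c, grid, geom) for c in clusters]
            silhouette = silhouette_index(clusters)
            if silhouette is not None:
                variables.append(NumericStateVariableRecord(
                    name="avgClusterednessClusters", value=silhouette))
        timepoints.append(Timepoint(value=t, spatialEntities=entities,
                                    numericStateVariables=variables))
    experiment = Experiment(timepoints=timepoints)
    experiment.validate(resolved=True)
    return experiment
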