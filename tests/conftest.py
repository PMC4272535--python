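import numpy as np
import pytest

from stmc.measures import SpaceGeometry
from stmc.patterns import Region


@pytest.fixture
def geom_101():
    return SpaceGeometry(rows=101, cols=101)


def make_point_region(x: float, y: float) -> Region:
    """Single-pixel region with its centroid at (x, y)."""
    return Region(outer_contour=np.array([[x, y]], dtype=float),
                  positions=frozenset([(int(round(y)), int(round(x)))]))


def make_square_region(x0: int, y0: int, side: int) -> Region:
    """Axis-aligned filled square of the given side, pixel-centre contour."""
    s = side - 1
    contour = np.array([[x0, y0], [x0 + s, y0], [x0 + s, y0 + s], [x0, y0 + s]],
                       dtype=float)
    positions = frozenset((y0 + r, x0 + c) for r in range(side) for c in range(side))
    return Region(outer_contour=contour, positions=positions)


@pytest.fixture
def random_region_factory():
    def factory(rng: np.random.Generator, n: int, span: float = 100.0):
        return [make_point_region(float(rng.uniform(0, span)),
                                  float(rng.uniform(0, span)))
                for _ in range(n)]
    return factory
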