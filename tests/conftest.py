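import numpy as np
import pytest

from trisync.synthetic import PatternSpec

#: One representative noise-free spec per oscillating pattern class.
PATTERN_SPECS = {
    "R": PatternSpec("R", amplitude=0.3, frequency=0.5),
    "PA1": PatternSpec("PA1", amplitude=0.3, frequency=0.5, base=1.0),
    "PA2": PatternSpec("PA2", amplitude=0.3, frequency=0.5, base=1.5),
    "PI1": PatternSpec("PI1", amplitude=0.3, frequency=0.4, base=0.9),
    "PI2": PatternSpec("PI2", amplitude=0.25, frequency=0.4, base=1.2),
}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_triangles(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random non-degenerate triangles as (n, 3, 2) vertex arrays."""
    pts = rng.uniform(0.0, 6.0, size=(n, 3, 2))
    # reject near-degenerate triples (tiny signed area) and redraw
    def area(p):
        u = p[:, 1] - p[:, 0]
        w = p[:, 2] - p[:, 0]
        return np.abs(u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0]) / 2.0
    bad = area(pts) < 1e-3
    while bad.any():
        pts[bad] = rng.uniform(0.0, 6.0, size=(int(bad.sum()), 3, 2))
        bad = area(pts) < 1e-3
    return pts
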