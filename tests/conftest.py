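import math

import numpy as np
import pytest


def placement_oracle(lam: float, n_discs: int, seed: int) -> tuple[float, int]:
    """Monte-Carlo co-capture oracle: molecules scattered uniformly on a
    large plane at 253/um^2, discs of the area giving mean occupancy ``lam``
    dropped at random positions.  Returns the empirical P(K >= 2 | K >= 1)
    and the number of occupied discs it was estimated from."""
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    density = 253.0
    radius = np.sqrt(lam / (np.pi * density))
    side = 40.0
    n_pts = rng.poisson(density * side * side)
    pts = rng.uniform(0, side, size=(n_pts, 2))
    centers = rng.uniform(radius, side - radius, size=(n_discs, 2))
    k = cKDTree(pts).query_ball_point(centers, radius, return_length=True)
    occupied = k[k >= 1]
    return float((occupied >= 2).sum() / occupied.size), int(occupied.size)


def binom_pmf(w: int, s: int, r: float) -> float:
    """Independent binomial oracle: C(s,w) r^w (1-r)^(s-w), pure stdlib."""
    if w < 0 or w > s:
        return 0.0
    return math.comb(s, w) * r**w * (1.0 - r) ** (s - w)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def staircase():
    """Noiseless 3-step bleaching trace: 300 -> 200 -> 100 -> 0."""
    return np.concatenate(
        [np.full(30, 300.0), np.full(30, 200.0), np.full(30, 100.0), np.full(30, 0.0)]
    )
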