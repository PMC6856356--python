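import numpy as np
import pytest
from shapely.geometry import Polygon

from woundtrack.trajectories import Track


@pytest.fixture
def square_owa() -> Polygon:
    """Unit test owa: the square [0, 10] x [0, 10] µm."""
    return Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_track(points, track_id=0, dt=30.0) -> Track:
    """Track from a list of (x, y) at a fixed frame interval."""
    pts = np.asarray(points, dtype=float)
    t = np.arange(len(pts)) * dt
    return Track(track_id, t, pts[:, 0], pts[:, 1])


def brute_force_cooc(image, mask, n_levels, offset, symmetric=False):
    """Independent all-pairs oracle for the co-occurrence matrix.

    Walks every pixel with a double loop and counts quantized-level pairs at
    the stated offset when both ends are inside the mask.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    h, w = image.shape
    counts = np.zeros((n_levels, n_levels))
    dy, dx = offset

    def level(v):
        if hi == lo:
            return 0
        q = int(np.floor((v - lo) / (hi - lo) * n_levels))
        return min(max(q, 0), n_levels - 1)

    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if not (0 <= r2 < h and 0 <= c2 < w):
                continue
            if mask[r, c] and mask[r2, c2]:
                counts[level(image[r, c]), level(image[r2, c2])] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


def brute_force_contrast(counts):
    n = counts.shape[0]
    p = counts / counts.sum()
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += (i - j) ** 2 * p[i, j]
    return total
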