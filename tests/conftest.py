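import numpy as np
import pytest

from pigweigh.cloud import PointCloud
from pigweigh.synthetic import SyntheticPigSpec, sample_pig_surface


@pytest.fixture
def rng():
    return np.random.default_rng(20240131)


@pytest.fixture
def random_cloud(rng):
    """1000 scattered points at pig-like depths, with colors."""
    pts = rng.uniform([-1.0, -0.6, 2.0], [1.0, 0.6, 2.7], size=(1000, 3))
    colors = rng.integers(0, 256, size=(1000, 3)).astype(np.uint8)
    return PointCloud(pts, colors, source_id="random")


@pytest.fixture(scope="session")
def pig_cloud():
    """A clean synthetic pig surface (no artifacts), 4000 points."""
    return sample_pig_surface(SyntheticPigSpec(seed=7), n_raw=4000)


def assert_subsequence(sub: PointCloud, full: PointCloud):
    """Every filter output must be the input with some points deleted."""
    idx = []
    j = 0
    for p in sub.points:
        while j < len(full) and not np.array_equal(full.points[j], p):
            j += 1
        assert j < len(full), "output point missing from input (or reordered)"
        idx.append(j)
        j += 1
    if sub.colors is not None:
        assert np.array_equal(sub.colors, full.colors[idx])
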