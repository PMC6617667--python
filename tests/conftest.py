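import math

import numpy as np
import pytest

from l1npi.cloud_io import pairwise_distances
from l1npi.image import ImageGrid
from l1npi.synthetic import make_hexagon
from l1npi.vr import compute_persistence, build_vr_filtration

SQRT3 = math.sqrt(3.0)


@pytest.fixture(scope="session")
def hexagon_cloud():
    return make_hexagon(1.0)


@pytest.fixture(scope="session")
def hexagon_diagram(hexagon_cloud):
    dm = pairwise_distances(hexagon_cloud)
    f = build_vr_filtration(dm, delta_max=2.5, max_dim=3)
    return compute_persistence(f, max_degree=2)


@pytest.fixture
def small_grid():
    return ImageGrid((0.0, 2.0), (0.0, 1.0), nx=10, ny=10, sigma=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_cloud(rng, n, scale=1.0):
    from l1npi.cloud_io import PointCloud

    return PointCloud(rng.uniform(0.0, scale, (n, 3)))
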