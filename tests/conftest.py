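import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from impactnet import Connectome, gen_atlas

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def path3():
    """Unit-weight chain A-B-C on regions 0-1-2."""
    w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return Connectome(w, (0, 1, 2))


@pytest.fixture
def complete4():
    """Complete unit-weight graph on 4 regions."""
    w = np.ones((4, 4)) - np.eye(4)
    return Connectome(w, (0, 1, 2, 3))


@pytest.fixture
def star5():
    """Star with hub region 0 and four leaves."""
    w = np.zeros((5, 5))
    w[0, 1:] = w[1:, 0] = 1.0
    return Connectome(w, tuple(range(5)))


@pytest.fixture
def toy_atlas():
    return gen_atlas(n_regions=5, n_hubs=1, n_strain_regions=1, seed=0)


def random_connectome(n, density, seed, weight_choices=None):
    """Random symmetric weighted test graph (not necessarily connected)."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(iu[0].size) < density
    if weight_choices is None:
        vals = rng.random(iu[0].size) + 0.1
    else:
        vals = rng.choice(weight_choices, size=iu[0].size).astype(float)
    w[iu] = mask * vals
    w = w + w.T
    return Connectome(w, tuple(range(n)))
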