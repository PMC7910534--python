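import numpy as np
import pytest

import flowstack as fs


def random_locations(seed, n, pop_min=3000.0, pop_max=25000.0, side=500.0):
    """Seeded random projected region set used across tests."""
    rng = np.random.default_rng(seed)
    return fs.LocationSet(
        ids=tuple(f"r{i}" for i in range(n)),
        coords=rng.uniform(0.0, side, size=(n, 2)),
        populations=np.exp(rng.uniform(np.log(pop_min), np.log(pop_max), size=n)),
    )


@pytest.fixture
def collinear_locs():
    """Three collinear regions: A(0,0) pop 10, B(5,0) pop 20, C(10,0) pop 30."""
    return fs.LocationSet(
        ids=("A", "B", "C"),
        coords=[(0.0, 0.0), (5.0, 0.0), (10.0, 0.0)],
        populations=[10.0, 20.0, 30.0],
    )


@pytest.fixture
def toy_locs():
    return random_locations(7, 8)


@pytest.fixture
def toy_geom(toy_locs):
    return fs.PairwiseGeometry.from_locations(toy_locs)


@pytest.fixture(scope="session")
def mixture_data():
    """30-region gravity + intervening-opportunities mixture with Poisson
    noise — a dataset no single base model generates."""
    scenario = fs.gravity_io_mixture_scenario(n_regions=30, seed=5)
    return fs.generate(scenario)
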