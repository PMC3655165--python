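import numpy as np
import pytest

import dietghg as dg


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world: 50 countries x 47 years, seed 1."""
    return dg.simulate_world(dg.WorldConfig(seed=1))


@pytest.fixture(scope="session")
def default_map(default_world):
    """A 4x2x2 SOM trained on the default world."""
    data = default_world.food[list(dg.FOOD_GROUPS) + ["total_kcal"]].to_numpy(float)
    return dg.train_som(data, dg.SOMConfig(grid_dims=(4, 2, 2), seed=1))


@pytest.fixture(scope="session")
def default_labels(default_world, default_map):
    return dg.assign_patterns(default_map, default_world.food)


@pytest.fixture(scope="session")
def small_world():
    """A quick 12-country x 15-year world for cheap integration tests."""
    return dg.simulate_world(dg.WorldConfig(n_countries=12, year_range=(1993, 2007), seed=7))


@pytest.fixture(scope="session")
def noiseless_world():
    """All generator noise off: compositions sit exactly on their archetypes."""
    return dg.simulate_world(
        dg.WorldConfig(
            n_countries=20,
            year_range=(1998, 2007),
            seed=3,
            concentration=None,
            total_sd_ln=0.0,
            impact_sd_ln=0.0,
            transition_rate=0.0,
        )
    )


def random_som_map(rng: np.random.Generator, max_nodes: int = 20) -> dg.SOMMap:
    """A random small map (random lattice, random distinct weights)."""
    while True:
        ndim = rng.integers(1, 4)
        dims = tuple(int(d) for d in rng.integers(1, 5, size=ndim))
        n = int(np.prod(dims))
        if 3 <= n <= max_nodes:
            break
    d = int(rng.integers(2, 6))
    coords = dg.som.lattice_coords(dims)
    weights = rng.normal(size=(n, d))
    return dg.SOMMap(
        grid_dims=dims,
        node_coords=coords,
        weights=weights,
        scale_mean=np.zeros(d),
        scale_sd=np.ones(d),
    )
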