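import logging
import warnings

import numpy as np
import pytest

from popfuse.grids import COUNT, GridGeometry, PopulationGrid, ZoneMap
from popfuse.synthetic import WorldConfig, make_products, make_world

logging.getLogger("popfuse").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240124)


@pytest.fixture
def geometry():
    return GridGeometry(west=-10.0, north=10.0, dx=1.0, dy=1.0)


@pytest.fixture
def small_grid(geometry):
    values = np.arange(100, dtype=float).reshape(10, 10)
    return PopulationGrid(values=values, geometry=geometry, unit=COUNT,
                          year=2000, product_id="test")


@pytest.fixture
def three_zone_map(geometry):
    labels = np.zeros((10, 10), dtype=int)
    labels[:5, :5] = 1
    labels[:5, 5:] = 2
    labels[5:, :] = 3
    return ZoneMap(labels=labels, geometry=geometry, level="level0",
                   code_lookup={1: "AAA", 2: "BBB", 3: "CCC"})


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic study system used across screening/fusion tests."""
    config = WorldConfig(seed=20240124)
    world = make_world(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        products, planted = make_products(world)
    return world, products, planted
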