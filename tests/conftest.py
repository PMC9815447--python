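import logging

import pytest
from shapely.geometry import Point

from distcost.region_model import Facility, Region, SpatialUnit
from distcost.road_network import RoadGraph
from distcost.synthetic_region import ScenarioConfig, generate

# snap-gap warnings are expected in high-jitter sweeps; keep test output clean
logging.getLogger("distcost.road_network").setLevel(logging.ERROR)
logging.getLogger("distcost.validator").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_scenario():
    """One default synthetic scenario shared by read-only tests."""
    return generate(ScenarioConfig(seed=11))


@pytest.fixture(scope="session")
def identity_scenario():
    """No address jitter, full sampling, deterministic case counts: the two
    arms must agree exactly."""
    return generate(
        ScenarioConfig(seed=5, jitter_sd=0.0, sampling_fraction=1.0,
                       case_model="expected")
    )


@pytest.fixture()
def path_region():
    """3 units on a path graph: facility -- a(1000m) -- b(1500m) -- c(3000m)."""
    nodes = {
        "f": (0.0, 0.0),
        "a": (1000.0, 0.0),
        "b": (2500.0, 0.0),
        "c": (5500.0, 0.0),
    }
    edges = [("f", "a", 1000.0), ("a", "b", 1500.0), ("b", "c", 3000.0)]
    graph = RoadGraph(nodes, edges)
    units = [
        SpatialUnit("u1", "c1", 100, geometry=Point(1000.0, 0.0)),
        SpatialUnit("u2", "c1", 200, geometry=Point(2500.0, 0.0)),
        SpatialUnit("u3", "c2", 300, geometry=Point(5500.0, 0.0)),
    ]
    region = Region(units, name="path")
    facility = Facility("f0", (0.0, 0.0))
    return region, graph, facility
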