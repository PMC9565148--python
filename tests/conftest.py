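import numpy as np
import pandas as pd
import pytest

import accesslogit as al


@pytest.fixture(scope="session")
def small_config():
    return al.RegionConfig(
        n_zones=12,
        n_resources={"park": 8, "grocery": 5, "library": 4},
        extent=(10.0, 20.0),
        spine_x=5.0,
        n_device_trips=40_000,
        n_trips=1_500,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_region(small_config):
    return al.generate(small_config)


@pytest.fixture(scope="session")
def park_dataset(small_region, small_config):
    r = small_region
    return al.build_dataset(
        r.flows["park"], r.resources["park"], r.skims["park"],
        r.specs["park"], n_trips=small_config.n_trips,
        n_alt=small_config.n_alt, seed=small_config.seed,
    )


@pytest.fixture
def toy_zones():
    return al.Zones(pd.DataFrame({
        "zone_id": ["A", "B", "C"],
        "x": [0.0, 1.0, 2.0],
        "y": [0.0, 0.0, 0.0],
        "households": [100, 200, 50],
        "frac_low_income": [0.25, 0.1, 0.6],
    }))


@pytest.fixture
def toy_parks():
    return al.Resources(pd.DataFrame({
        "resource_id": ["p1", "p2"],
        "x": [0.5, 1.5],
        "y": [0.0, 0.0],
        "acres": [np.e, 10.0],
        "playground": [1, 0],
        "volleyball": [0, 1],
        "basketball": [0, 0],
        "tennis": [1, 0],
    }), "park")


def make_skims(rows):
    """Skim table from (zone, resource, t_auto, t_walk, d_walk) tuples;
    transit left unavailable."""
    return al.SkimSet(pd.DataFrame(
        rows, columns=["zone_id", "resource_id", "t_auto", "t_walk", "d_walk"]
    ))


@pytest.fixture
def toy_skims():
    return make_skims([
        ("A", "p1", 3.0, 8.0, 0.4),
        ("A", "p2", 6.0, 20.0, 1.0),
        ("B", "p1", 4.0, 10.0, 0.5),
        ("B", "p2", 3.0, 7.0, 0.35),
        ("C", "p1", 10.0, 30.0, 1.6),
        ("C", "p2", 5.0, 12.0, 0.6),
    ])
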