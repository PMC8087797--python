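import numpy as np
import pytest

from fluvialfire import synthetic_data as sd
from fluvialfire.types import BurnGenSpec, DOSagSpec, HortonParams

REGION = (0.0, 0.0, 80.0, 50.0)


@pytest.fixture(scope="session")
def region():
    return REGION


@pytest.fixture(scope="session")
def network():
    params = HortonParams(r_b=2.0, r_l=2.0, mean_l1=0.5, max_order=6, length_cv=0.2)
    return sd.generate_network(params, REGION, seed=5)


@pytest.fixture(scope="session")
def burn_spec():
    return BurnGenSpec(
        n_fires=30,
        area_log_mean=2.0,
        area_log_sd=0.8,
        severity_fractions={
            "unburned": 0.2,
            "low": 0.3,
            "moderate": 0.2,
            "high": 0.2,
            "masked": 0.1,
        },
        year_range=(1984, 2014),
    )


@pytest.fixture(scope="session")
def scars(burn_spec):
    return sd.generate_burn_scars(REGION, burn_spec, seed=3)


@pytest.fixture(scope="session")
def ecoregions():
    return sd.generate_ecoregions(REGION, 5, seed=4)


@pytest.fixture(scope="session")
def do_spec():
    return DOSagSpec(
        station_distances=[68.0, 82.0, 99.0, 117.0],
        baseline_do=7.2,
        components=(5.0, 0.01, 0.0, 0.0),
        event_times=[
            "2011-07-20 12:00",
            "2011-07-24 06:00",
            "2011-08-01 18:00",
            "2011-08-08 00:00",
        ],
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def do_series(do_spec):
    return sd.generate_do_series(do_spec, seed=6)


def random_tree_topology(n: int, rng: np.random.Generator) -> dict:
    """Random rooted tree on n nodes: node i attaches to a random earlier node."""
    topo = {"n0": None}
    for i in range(1, n):
        topo[f"n{i}"] = f"n{int(rng.integers(0, i))}"
    return topo


def strahler_oracle(topology: dict) -> dict:
    """Straightforward recursive Strahler ordering, independent of the package."""
    children = {}
    for c, p in topology.items():
        children.setdefault(p, []).append(c)

    def order(node):
        kids = children.get(node, [])
        if not kids:
            return 1
        ko = sorted((order(k) for k in kids), reverse=True)
        return ko[0] + 1 if len(ko) > 1 and ko[0] == ko[1] else ko[0]

    return {node: order(node) for node in topology}
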