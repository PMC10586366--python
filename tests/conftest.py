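"""Shared fixtures: small synthetic scenarios and hand-built networks."""

from __future__ import annotations

import numpy as np
import pytest

from aquarisk.scenario import (
    Reach,
    ReachNetwork,
    SimulationPeriod,
    compute_strahler,
)
from aquarisk.synthetic import SyntheticParams, generate_synthetic_catchment


def make_chain(n: int, **reach_kwargs) -> ReachNetwork:
    """Linear chain r0 <- r1 <- ... <- r{n-1}; r0 is the outlet."""
    reaches = []
    for i in range(n):
        reaches.append(
            Reach(
                id=f"r{i}",
                length=100.0,
                downstream_id=None if i == 0 else f"r{i-1}",
                drainage_area=float(n - i) * 1e5,
                **reach_kwargs,
            )
        )
    net = ReachNetwork(reaches)
    compute_strahler(net)
    return net


def random_tree_network(n: int, rng: np.random.Generator) -> ReachNetwork:
    """Random tree with arbitrary junction degree (not capped at 2), for
    stressing the Strahler rule beyond what the generator produces."""
    reaches = [Reach(id="r0", length=50.0, drainage_area=n * 1e4)]
    for i in range(1, n):
        parent = int(rng.integers(0, i))
        reaches.append(
            Reach(id=f"r{i}", length=50.0, downstream_id=f"r{parent}")
        )
    net = ReachNetwork(reaches)
    # drainage areas consistent with topology
    up = net.upstream_map()
    for rid in net.topological_order():
        net[rid].drainage_area = 1e4 + sum(net[u].drainage_area for u in up[rid])
    return net


@pytest.fixture(scope="session")
def small_scenario():
    """30-reach catchment, 1 warm-up + 2 assessment years."""
    params = SyntheticParams()
    params.period = SimulationPeriod(warmup_years=1, assessment_years=2,
                                     start_year=2000)
    return generate_synthetic_catchment(30, seed=7, params=params)


@pytest.fixture(scope="session")
def small_hydro(small_scenario):
    from aquarisk.hydrology import build_hydro_series

    return build_hydro_series(small_scenario.network, small_scenario.discharge)
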