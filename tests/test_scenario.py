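"""Scenario model: topology validation, Strahler ordering, geometry
assignment, temperature preprocessing, serialization, synthetic generator."""

from __future__ import annotations

import filecmp
import json

import numpy as np
import pandas as pd
import pytest

from aquarisk.errors import ConfigurationError, SchemaError, TopologyError
from aquarisk.scenario import (
    GeometrySpec,
    Reach,
    ReachNetwork,
    WindRose,
    assign_geometry_by_strahler,
    compute_strahler,
    load_scenario,
    preprocess_temperature,
    save_scenario,
)
from aquarisk.synthetic import SyntheticParams, generate_synthetic_catchment
from conftest import make_chain, random_tree_network


# ---------------------------------------------------------------------------
# topology validation
# ---------------------------------------------------------------------------

class TestTopology:
    def test_two_outlets_rejected(self):
        with pytest.raises(TopologyError, match="exactly one outlet"):
            ReachNetwork([Reach(id="a", length=1.0), Reach(id="b", length=1.0)])

    def test_dangling_downstream_rejected(self):
        with pytest.raises(TopologyError, match="does not resolve"):
            ReachNetwork(
                [Reach(id="a", length=1.0),
                 Reach(id="b", length=1.0, downstream_id="ghost")]
            )

    def test_cycle_rejected(self):
        with pytest.raises(TopologyError):
            ReachNetwork(
                [
                    Reach(id="out", length=1.0),
                    Reach(id="a", length=1.0, downstream_id="b"),
                    Reach(id="b", length=1.0, downstream_id="a"),
                ]
            )

    def test_invalid_reach_fields_rejected(self):
        with pytest.raises(SchemaError):
            ReachNetwork([Reach(id="a", length=-5.0)])


# ---------------------------------------------------------------------------
# Strahler ordering
# ---------------------------------------------------------------------------

def _strahler_oracle(net: ReachNetwork) -> dict[str, int]:
    """Independent recursive implementation of the classical rule."""
    up = net.upstream_map()

    def order(rid: str) -> int:
        ups = up[rid]
        if not ups:
            return 1
        orders = sorted((order(u) for u in ups), reverse=True)
        if len(orders) >= 2 and orders[0] == orders[1]:
            return orders[0] + 1
        return orders[0]

    import sys
    sys.setrecursionlimit(10000)
    return {r.id: order(r.id) for r in net}


class TestStrahler:
    def test_linear_chain_is_all_order_one(self):
        net = make_chain(5)
        assert {r.strahler_order for r in net} == {1}

    def test_two_headwaters_join_to_order_two(self):
        net = ReachNetwork(
            [
                Reach(id="out", length=10.0, drainage_area=3e4),
                Reach(id="l", length=10.0, downstream_id="out", drainage_area=1e4),
                Reach(id="r", length=10.0, downstream_id="out", drainage_area=1e4),
            ]
        )
        compute_strahler(net)
        assert net["l"].strahler_order == net["r"].strahler_order == 1
        assert net["out"].strahler_order == 2

    def test_unequal_junction_propagates_max(self):
        # order-2 meets order-1: downstream stays order 2
        reaches = [
            Reach(id="out", length=10.0),
            Reach(id="j", length=10.0, downstream_id="out"),
            Reach(id="a", length=10.0, downstream_id="j"),
            Reach(id="b", length=10.0, downstream_id="j"),
            Reach(id="c", length=10.0, downstream_id="out"),
        ]
        net = ReachNetwork(reaches)
        compute_strahler(net)
        assert net["out"].strahler_order == 2

    def test_matches_recursive_oracle_on_random_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(2, 120))
            net = random_tree_network(n, rng)
            compute_strahler(net)
            expected = _strahler_oracle(net)
            assert {r.id: r.strahler_order for r in net} == expected


# ---------------------------------------------------------------------------
# geometry assignment
# ---------------------------------------------------------------------------

class TestGeometryAssignment:
    def _net(self):
        net = ReachNetwork(
            [
                Reach(id="out", length=10.0, drainage_area=3e4),
                Reach(id="l", length=20.0, downstream_id="out", drainage_area=1e4),
                Reach(id="r", length=30.0, downstream_id="out", drainage_area=1e4),
            ]
        )
        return compute_strahler(net)

    def test_widths_follow_orders_and_lengths_untouched(self):
        net = self._net()
        lookup = {
            1: GeometrySpec(1.0, 1.0, 0.03, 1.0),
            2: GeometrySpec(2.0, 1.5, 0.04, 2.5),
        }
        assign_geometry_by_strahler(net, lookup)
        assert net["l"].bottom_width == 1.0
        assert net["out"].bottom_width == 2.0
        assert net["out"].bank_slope == 1.5
        assert [net[r].length for r in ("out", "l", "r")] == [10.0, 20.0, 30.0]

    def test_missing_order_raises(self):
        net = self._net()
        with pytest.raises(ConfigurationError, match="order"):
            assign_geometry_by_strahler(net, {1: GeometrySpec(1, 1, 0.03, 1)})

    def test_identity_lookup_gives_uniform_network(self):
        net = self._net()
        spec = GeometrySpec(1.5, 1.0, 0.03, 2.0)
        assign_geometry_by_strahler(net, {1: spec, 2: spec})
        assert len({r.bottom_width for r in net}) == 1


# ---------------------------------------------------------------------------
# temperature preprocessing
# ---------------------------------------------------------------------------

class TestTemperature:
    def test_three_day_trailing_mean(self):
        idx = pd.date_range("2000-01-01", periods=4)
        out = preprocess_temperature(pd.Series([10.0, 12.0, 14.0, 16.0], index=idx))
        assert out.iloc[3] == pytest.approx(12.0)  # mean of days 1-3

    def test_first_days_padded_with_first_mean(self):
        idx = pd.date_range("2000-01-01", periods=6)
        out = preprocess_temperature(
            pd.Series([3.0, 6.0, 9.0, 0.0, 0.0, 0.0], index=idx)
        )
        assert list(out.iloc[:4]) == [6.0, 6.0, 6.0, 6.0]

    def test_matches_brute_force_windows(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(10, 5, 60)
        idx = pd.date_range("2000-01-01", periods=60)
        out = preprocess_temperature(pd.Series(vals, index=idx))
        for i in range(3, 60):
            assert out.iloc[i] == pytest.approx(vals[i - 3:i].mean(), rel=1e-12)
        assert len(out) == 60


# ---------------------------------------------------------------------------
# wind rose validation
# ---------------------------------------------------------------------------

class TestWindRose:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(SchemaError, match="sum to 1"):
            WindRose(np.array([0.0, 180.0, 360.0]), np.array([0.5, 0.4]))

    def test_bins_must_partition_circle(self):
        with pytest.raises(SchemaError):
            WindRose(np.array([0.0, 180.0, 350.0]), np.array([0.5, 0.5]))


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

@pytest.fixture()
def quick_params():
    p = SyntheticParams()
    from aquarisk.scenario import SimulationPeriod
    p.period = SimulationPeriod(warmup_years=0, assessment_years=1,
                                start_year=2001)
    return p


class TestGenerator:
    def test_single_reach_catchment(self, quick_params):
        b = generate_synthetic_catchment(1, seed=0, params=quick_params)
        assert len(b.network) == 1
        assert b.network.outlet.strahler_order == 1

    def test_same_seed_is_byte_identical(self, quick_params, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        save_scenario(generate_synthetic_catchment(40, 9, quick_params), d1)
        save_scenario(generate_synthetic_catchment(40, 9, quick_params), d2)
        for f in d1.iterdir():
            assert filecmp.cmp(f, d2 / f.name, shallow=False), f.name

    def test_lengths_within_configured_range(self, quick_params):
        b = generate_synthetic_catchment(150, seed=3, params=quick_params)
        lengths = np.array([r.length for r in b.network])
        assert lengths.min() >= 5.0 and lengths.max() <= 110.0
        assert 80 < np.median(lengths) < 110

    def test_headwater_share_near_55_percent(self, quick_params):
        shares = []
        for seed in range(5):
            b = generate_synthetic_catchment(200, seed=seed, params=quick_params)
            orders = [r.strahler_order for r in b.network]
            shares.append(100.0 * orders.count(1) / len(orders))
        assert 45.0 < float(np.mean(shares)) < 65.0

    def test_generated_network_valid_and_single_outlet(self, quick_params):
        b = generate_synthetic_catchment(80, seed=1, params=quick_params)
        assert sum(1 for r in b.network if r.downstream_id is None) == 1
        b.network.validate_drainage_monotone()
        assert all(r.strahler_order >= 1 for r in b.network)

    def test_scenario_roundtrip(self, quick_params, tmp_path):
        b = generate_synthetic_catchment(25, seed=4, params=quick_params)
        save_scenario(b, tmp_path / "scen")
        b2 = load_scenario(tmp_path / "scen")
        assert b2.network.reach_ids == b.network.reach_ids
        for rid in b.network.reach_ids:
            assert b2.network[rid].drainage_area == pytest.approx(
                b.network[rid].drainage_area)
            assert b2.network[rid].strahler_order == b.network[rid].strahler_order
        assert len(b2.orchards) == len(b.orchards)
        assert np.allclose(b2.discharge.to_numpy(), b.discharge.to_numpy())
        # loader re-applies the trailing-mean preprocessing
        assert np.allclose(b2.temperature.to_numpy(), b.temperature.to_numpy())

    def test_missing_file_raises_schema_error(self, tmp_path):
        with pytest.raises(SchemaError, match="missing"):
            load_scenario(tmp_path)
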