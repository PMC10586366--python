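"""Water-sediment fate: partitioning, degradation, the single-reach step,
and network routing with its mass ledger."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from aquarisk.fate import (
    MassLedger,
    WaterSedimentState,
    degrade,
    dissolved_fraction,
    route_network,
    step_reach,
)
from aquarisk.hydrology import HydroSeries
from aquarisk.scenario import Reach, ReachNetwork, SubstanceProperties
from conftest import make_chain


def inert_substance(**overrides) -> SubstanceProperties:
    """Substance with all loss/exchange processes switched off unless
    overridden — isolates individual processes in tests."""
    base = dict(
        koc=1.0, dt50_water=1e15, dt50_sediment=1e15,
        molar_activation_energy=0.0, volatilization_rate=0.0,
        sed_exchange_velocity=0.0, suspended_solids=0.0,
    )
    base.update(overrides)
    return SubstanceProperties(**base)


def uniform_hydro(net: ReachNetwork, n_hours: int, q_m3h: float,
                  volume_m3: float, start="2000-01-01") -> HydroSeries:
    index = pd.date_range(start, periods=n_hours, freq="h")
    n_r = len(net.reach_ids)
    shape = (n_hours, n_r)
    return HydroSeries(
        index=index,
        reach_ids=net.reach_ids,
        discharge=np.full(shape, q_m3h),
        depth=np.full(shape, 0.5),
        velocity=np.full(shape, q_m3h / 1.0),
        volume=np.full(shape, volume_m3),
    )


def const_temperature(index: pd.DatetimeIndex, value: float = 20.0) -> pd.Series:
    days = pd.date_range(index[0].normalize(), index[-1].normalize(), freq="D")
    return pd.Series(value, index=days)


def drift_pulse(reach_id: str, when: str, mass: float) -> pd.DataFrame:
    return pd.DataFrame(
        {"reach_id": [reach_id], "timestamp": [pd.Timestamp(when)],
         "mass_ug": [mass], "areic_ug_per_m2": [np.nan]}
    )


class TestDissolvedFraction:
    def test_no_suspended_solids_all_dissolved(self):
        assert dissolved_fraction(inert_substance()) == 1.0

    def test_formula_for_strong_sorber(self):
        s = inert_substance(koc=1.024e6, foc_suspended=0.1, suspended_solids=1.5e-5)
        assert dissolved_fraction(s) == pytest.approx(1.0 / (1.0 + 1.536), rel=1e-12)

    def test_infinite_sorption_limit(self):
        s = inert_substance(koc=1e30, suspended_solids=1e-5)
        assert dissolved_fraction(s) < 1e-20


class TestDegradation:
    def test_half_life_halves_mass_at_reference_temperature(self):
        s = inert_substance(dt50_water=43.9)
        out = degrade(100.0, 43.9, s.ref_temp, s, dt_h=43.9 * 24.0)
        assert out == pytest.approx(50.0, rel=1e-12)

    def test_zero_activation_energy_ignores_temperature(self):
        s = inert_substance(dt50_water=10.0, molar_activation_energy=0.0)
        cold = degrade(100.0, 10.0, 2.0, s, 24.0)
        warm = degrade(100.0, 10.0, 30.0, s, 24.0)
        assert cold == warm

    def test_warmer_degrades_faster(self):
        s = SubstanceProperties()
        warm = degrade(100.0, 43.9, 30.0, s, 240.0)
        cold = degrade(100.0, 43.9, 5.0, s, 240.0)
        assert warm < cold


class TestStepReach:
    REACH = Reach(id="x", length=100.0, bottom_width=1.0, drainage_area=1e4)

    def test_no_input_no_mass_stays_zero(self):
        s = inert_substance()
        state, cw, out = step_reach(
            WaterSedimentState(), 0.0, 0.0, self.REACH, 360.0, 60.0, s, 20.0
        )
        assert state.water_mass == 0.0 and state.sediment_mass == 0.0
        assert cw == 0.0 and out == 0.0

    def test_cstr_pulse_matches_analytic_hourly_averages(self):
        """Pure advection: C(t) = (M0/V) exp(-Q t / V); hourly averages
        must match the closed-form integral within 0.1%."""
        s = inert_substance()
        q, v, m0 = 600.0, 200.0, 1e6  # residence time 20 min
        k = q / v  # 1/h
        state = WaterSedimentState()
        inflow = m0
        for hour in range(6):
            state, cw, _ = step_reach(state, 0.0, inflow, self.REACH, q, v, s, 20.0)
            inflow = 0.0
            expected = (m0 / (1000.0 * v)) * (
                math.exp(-k * hour) - math.exp(-k * (hour + 1))
            ) / k
            assert cw == pytest.approx(expected, rel=1e-3)

    def test_exchange_conserves_total_mass_and_relaxes_partitioning(self):
        """Advection and degradation off, exchange on: water+sediment mass
        is constant while the split approaches the partitioning fixed
        point (water:sediment ratio ksw/kws)."""
        s = inert_substance(sed_exchange_velocity=0.05, foc_sediment=0.01)
        state = WaterSedimentState(water_mass=1000.0)
        v = 50.0
        history = []
        for _ in range(2000):
            state, _, out = step_reach(state, 0.0, 0.0, self.REACH, 0.0, v, s, 20.0)
            assert out == 0.0
            history.append((state.water_mass, state.sediment_mass))
        total = state.water_mass + state.sediment_mass
        assert total == pytest.approx(1000.0, rel=1e-9)
        from aquarisk.fate import _reach_exchange_coefficients
        cws, ksw, _ = _reach_exchange_coefficients(self.REACH, s)
        kws = cws / v
        eq_ratio = ksw / kws
        ratio = state.water_mass / state.sediment_mass
        assert ratio == pytest.approx(eq_ratio, rel=5e-2)

    def test_matches_network_kernel_on_two_reach_chain(self):
        """The vectorized routing kernel and the per-reach reference step
        must produce identical numbers."""
        net = make_chain(2)
        s = SubstanceProperties()
        hydro = uniform_hydro(net, 48, q_m3h=500.0, volume_m3=120.0)
        drift = drift_pulse("r1", "2000-01-01 12:00", 5e5)
        field, ledger = route_network(net, hydro, drift, s,
                                      const_temperature(hydro.index))
        # reference: manual loop, r1 (upstream) then r0 (outlet)
        st = {"r1": WaterSedimentState(), "r0": WaterSedimentState()}
        for h in range(48):
            add = 5e5 if h == 12 else 0.0
            st["r1"], cw1, out1 = step_reach(st["r1"], 0.0, add, net["r1"],
                                             500.0, 120.0, s, 20.0)
            st["r0"], cw0, out0 = step_reach(st["r0"], out1, 0.0, net["r0"],
                                             500.0, 120.0, s, 20.0)
            assert field.cw[h, field.column("r1")] == pytest.approx(cw1, rel=1e-12)
            assert field.cw[h, field.column("r0")] == pytest.approx(cw0, rel=1e-12)


class TestRouteNetwork:
    def test_chain_pulse_fully_exported_without_losses(self):
        net = make_chain(3)
        s = inert_substance()
        hydro = uniform_hydro(net, 24 * 14, q_m3h=800.0, volume_m3=100.0)
        drift = drift_pulse("r2", "2000-01-02 12:00", 1e6)
        field, ledger = route_network(net, hydro, drift, s,
                                      const_temperature(hydro.index))
        assert ledger.input == pytest.approx(1e6)
        assert ledger.exported_at_outlet == pytest.approx(1e6, rel=1e-6)
        ledger.validate(tol=1e-6)

    def test_reachability_determines_exposure(self, small_scenario, small_hydro):
        """Exactly the reaches downstream of a pulsed reach see nonzero
        concentration; an independent graph-reachability oracle defines
        'downstream'."""
        import networkx as nx
        net = small_scenario.network
        source = next(r.id for r in net if r.strahler_order == 1
                      and r.downstream_id is not None)
        drift = drift_pulse(source, str(small_hydro.index[100]), 1e6)
        field, _ = route_network(net, small_hydro, drift,
                                 small_scenario.substance,
                                 const_temperature(small_hydro.index))
        reachable = nx.descendants(net.to_digraph(), source) | {source}
        for rid in net.reach_ids:
            cmax = field.cw[:, field.column(rid)].max()
            if rid in reachable:
                assert cmax > 0.0, rid
            else:
                assert cmax == 0.0, rid

    def test_zero_drift_zero_field_and_ledger(self, small_scenario, small_hydro):
        empty = pd.DataFrame(columns=["reach_id", "timestamp", "mass_ug",
                                      "areic_ug_per_m2"])
        field, ledger = route_network(
            small_scenario.network, small_hydro, empty,
            small_scenario.substance, const_temperature(small_hydro.index),
        )
        assert field.cw.max() == 0.0
        assert ledger.input == ledger.stored == ledger.exported_at_outlet == 0.0

    def test_linearity_in_drift_mass(self, small_scenario, small_hydro):
        drift = drift_pulse("r0015", str(small_hydro.index[50]), 1e5)
        s = small_scenario.substance
        temp = const_temperature(small_hydro.index)
        f1, _ = route_network(small_scenario.network, small_hydro, drift, s, temp)
        drift2 = drift.copy()
        drift2["mass_ug"] *= 3.5
        f2, _ = route_network(small_scenario.network, small_hydro, drift2, s, temp)
        np.testing.assert_allclose(f2.cw, 3.5 * f1.cw, rtol=1e-9)

    def test_peak_dilutes_downstream_in_uniform_chain(self):
        """With discharge increasing downstream, the concentration peak of
        a single upstream pulse cannot grow along the path."""
        net = make_chain(4)
        index = pd.date_range("2000-01-01", periods=24 * 7, freq="h")
        n_r = 4
        # discharge grows downstream with drainage area; volume likewise
        q = np.array([net[r].drainage_area / 1e5 for r in net.reach_ids]) * 400.0
        hydro = HydroSeries(
            index=index, reach_ids=net.reach_ids,
            discharge=np.tile(q, (len(index), 1)),
            depth=np.full((len(index), n_r), 0.5),
            velocity=np.full((len(index), n_r), 100.0),
            volume=np.tile(q / 4.0, (len(index), 1)),  # 15-min residence
        )
        drift = drift_pulse("r3", "2000-01-01 06:00", 1e6)
        field, _ = route_network(net, hydro, drift, inert_substance(),
                                 const_temperature(index))
        peaks = [field.cw[:, field.column(f"r{i}")].max() for i in (3, 2, 1, 0)]
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))

    def test_exposure_pulse_is_short_relative_to_residence(self):
        """Concentration-time profiles after a drift event are peaky: the
        time above half of the peak in the dosed reach stays within an
        order of magnitude of the residence time."""
        net = make_chain(1)
        hydro = uniform_hydro(net, 24 * 3, q_m3h=600.0, volume_m3=150.0)
        drift = drift_pulse("r0", "2000-01-01 02:00", 1e6)
        field, _ = route_network(net, hydro, drift, SubstanceProperties(),
                                 const_temperature(hydro.index))
        cw = field.cw[:, 0]
        hours_above = float((cw > 0.5 * cw.max()).sum())
        residence_h = 150.0 / 600.0
        assert hours_above <= max(1.0, 10.0 * residence_h)

    def test_warmup_years_excluded_from_field(self, small_scenario, small_hydro):
        drift = drift_pulse("r0000", str(small_hydro.index[10]), 1e5)
        field, _ = route_network(
            small_scenario.network, small_hydro, drift,
            small_scenario.substance, const_temperature(small_hydro.index),
            period=small_scenario.period,
        )
        assert sorted(set(field.index.year)) == small_scenario.period.assessment_year_list


class TestMassLedger:
    def test_closure_error_and_validation(self):
        bad = MassLedger(input=100.0, exported_at_outlet=90.0)
        assert bad.closure_error() == pytest.approx(0.1)
        with pytest.raises(Exception):
            bad.validate(tol=1e-6)
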