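"""Synthetic catchment generator.

Emulates the kind of lowland orchard catchment the simulator targets: a
dendritic network of roughly 100 m reaches (lengths clipped to 5-110 m)
draining to a single outlet, a majority of headwater (order-1) reaches,
orchard polygons flanking a subset of reaches, a seasonal outlet discharge
with multiplicative noise, a seasonal daily temperature series, and a
single-mode wind rose.

The generator is the package's stand-in for real catchment geodata: every
draw comes from one seeded generator, so identical ``(n_reaches, seed,
params)`` produce byte-identical scenario directories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

from .errors import ConfigurationError
from .scenario import (
    ApplicationSetup,
    GeometrySpec,
    Orchard,
    Reach,
    ReachNetwork,
    ScenarioBundle,
    SimulationPeriod,
    SubstanceProperties,
    WindRose,
    assign_geometry_by_strahler,
    compute_strahler,
    preprocess_temperature,
)

__all__ = ["SyntheticParams", "default_geometry_lookup", "default_wind_rose",
           "generate_synthetic_catchment"]


def default_geometry_lookup(max_order: int = 6) -> dict[int, GeometrySpec]:
    """Illustrative Strahler-order -> channel geometry table.

    Widths grow roughly geometrically with order; Manning's n decreases
    slightly as channels get larger and cleaner.
    """
    lookup = {}
    for k in range(1, max_order + 1):
        width = 0.5 * 1.7 ** (k - 1)
        lookup[k] = GeometrySpec(
            bottom_width=round(width, 3),
            bank_slope=1.0,
            manning_n=round(max(0.025, 0.042 - 0.004 * (k - 1)), 4),
            drift_surface_width=round(width + 0.5, 3),
        )
    return lookup


def default_wind_rose() -> WindRose:
    """Eight-sector rose with a south-westerly dominance (maritime
    temperate climate)."""
    edges = np.arange(0.0, 361.0, 45.0)
    probs = np.array([0.08, 0.07, 0.09, 0.10, 0.13, 0.22, 0.18, 0.13])
    return WindRose(edges, probs)


@dataclass
class SyntheticParams:
    """Knobs of the synthetic catchment.

    branch_prob controls how often a new reach starts a junction instead of
    extending an existing headwater chain; the default is calibrated so a
    ~200-reach network has roughly 55% order-1 reaches.  local_area_m2 is
    the mean incremental drainage area contributed by one reach (~9 ha, a
    mid-size agricultural catchment divided into ~100 m reaches).
    specific_discharge is the long-term mean areal yield in L/s/km2.
    """

    branch_prob: float = 0.46
    mean_length: float = 100.0          # m
    length_sd: float = 15.0             # m
    length_range: tuple[float, float] = (5.0, 110.0)
    local_area_m2: float = 9.0e4
    slope_range: tuple[float, float] = (0.002, 0.01)
    orchard_fraction: float = 0.35      # fraction of reaches flanked by an orchard
    orchard_distance_range: tuple[float, float] = (3.0, 40.0)  # m edge-to-centreline
    orchard_along_m: float = 120.0      # orchard extent parallel to the reach
    orchard_across_m: float = 80.0      # orchard extent away from the reach
    specific_discharge: float = 10.0    # L/s/km2
    q_seasonal_amplitude: float = 0.6   # winter-peaked sinusoid
    q_peak_doy: int = 20                # day-of-year of the discharge maximum
    q_noise_sigma: float = 0.3          # lognormal sigma of daily noise
    q_noise_rho: float = 0.85           # AR(1) persistence of daily noise
    temp_mean: float = 10.0             # degC
    temp_amplitude: float = 8.0
    temp_peak_doy: int = 200
    temp_noise_sd: float = 1.5
    geometry_lookup: dict[int, GeometrySpec] = field(default_factory=default_geometry_lookup)
    wind_rose: WindRose = field(default_factory=default_wind_rose)
    substance: SubstanceProperties = field(default_factory=SubstanceProperties)
    application: ApplicationSetup = field(default_factory=ApplicationSetup)
    period: SimulationPeriod = field(default_factory=SimulationPeriod)


# ---------------------------------------------------------------------------

def _grow_tree(n: int, branch_prob: float, rng: np.random.Generator) -> list[int | None]:
    """Random dendritic tree: returns downstream parent index per node
    (node 0 is the outlet, parent None).

    Each new reach either extends a headwater tip or turns a pass-through
    reach into a junction (degree cap 2 upstream).
    """
    parent: list[int | None] = [None]
    n_up = [0]  # upstream children per node
    for i in range(1, n):
        tips = [j for j in range(i) if n_up[j] == 0]
        joinable = [j for j in range(i) if n_up[j] == 1]
        if joinable and (not tips or rng.random() < branch_prob):
            target = joinable[rng.integers(len(joinable))]
        else:
            target = tips[rng.integers(len(tips))]
        parent.append(target)
        n_up.append(0)
        n_up[target] += 1
    return parent


def _layout(parent: list[int | None], lengths: np.ndarray,
            rng: np.random.Generator) -> list[LineString]:
    """Planar embedding: outlet at the origin, reaches drawn as straight
    segments growing upstream with small random turns and +/-40 degree
    splits at junctions.  Overlaps are cosmetic only; no geometric
    computation depends on planarity."""
    n = len(parent)
    children: list[list[int]] = [[] for _ in range(n)]
    order = []
    for i, p in enumerate(parent):
        if p is not None:
            children[p].append(i)
    # upstream endpoint and upstream-pointing direction per node
    start = [None] * n  # downstream end of the segment
    theta = [0.0] * n
    start[0] = np.array([0.0, 0.0])
    theta[0] = math.pi / 2  # grow north
    geoms: list[LineString] = [None] * n  # type: ignore[list-item]
    stack = [0]
    while stack:
        j = stack.pop()
        end = start[j] + lengths[j] * np.array([math.cos(theta[j]), math.sin(theta[j])])
        # flow is upstream end -> downstream end
        geoms[j] = LineString([tuple(end), tuple(start[j])])
        kids = children[j]
        if len(kids) == 1:
            k = kids[0]
            start[k] = end
            theta[k] = theta[j] + rng.normal(0.0, math.radians(12.0))
            stack.append(k)
        elif len(kids) >= 2:
            signs = [1.0, -1.0]
            for k, s in zip(kids, signs):
                start[k] = end
                theta[k] = theta[j] + s * math.radians(40.0) + rng.normal(0.0, math.radians(8.0))
                stack.append(k)
    return geoms


def _orchard_polygon(line: LineString, dist: float, side: float,
                     along: float, across: float) -> Polygon:
    """Axis-aligned-to-the-reach rectangle whose near edge is ``dist`` from
    the reach centreline on the given side."""
    (x0, y0), (x1, y1) = line.coords[0], line.coords[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy)
    ux, uy = dx / norm, dy / norm
    nx_, ny_ = -uy * side, ux * side
    mx, my = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    half = along / 2.0
    near = (mx + nx_ * dist, my + ny_ * dist)
    pts = [
        (near[0] - ux * half, near[1] - uy * half),
        (near[0] + ux * half, near[1] + uy * half),
        (near[0] + ux * half + nx_ * across, near[1] + uy * half + ny_ * across),
        (near[0] - ux * half + nx_ * across, near[1] - uy * half + ny_ * across),
    ]
    return Polygon(pts)


def _outlet_discharge(index: pd.DatetimeIndex, mean_m3h: float,
                      p: SyntheticParams, rng: np.random.Generator) -> pd.Series:
    """Seasonal sinusoid times AR(1) lognormal daily noise, hourly index."""
    days = pd.date_range(index[0].normalize(), index[-1].normalize(), freq="D")
    doy = days.dayofyear.to_numpy(float)
    seasonal = 1.0 + p.q_seasonal_amplitude * np.cos(
        2.0 * math.pi * (doy - p.q_peak_doy) / 365.25
    )
    eps = rng.standard_normal(len(days))
    x = np.empty(len(days))
    x[0] = eps[0] * p.q_noise_sigma
    a = p.q_noise_rho
    innov_sd = p.q_noise_sigma * math.sqrt(1.0 - a * a)
    for i in range(1, len(days)):
        x[i] = a * x[i - 1] + innov_sd * eps[i]
    noise = np.exp(x - 0.5 * p.q_noise_sigma ** 2)
    q_day = mean_m3h * seasonal * noise
    daily = pd.Series(q_day, index=days)
    q_hour = daily.reindex(index.normalize()).to_numpy()
    return pd.Series(q_hour, index=index, name="discharge_m3_per_h")


def generate_synthetic_catchment(
    n_reaches: int, seed: int, params: SyntheticParams | None = None
) -> ScenarioBundle:
    """Generate a complete, validated synthetic landscape scenario.

    Parameters
    ----------
    n_reaches
        Number of stream reaches (>= 1).
    seed
        Seed for the generator's private random stream.
    params
        Generator settings; defaults emulate a mid-size lowland orchard
        catchment (see :class:`SyntheticParams`).
    """
    if n_reaches < 1:
        raise ConfigurationError("n_reaches must be >= 1")
    p = params or SyntheticParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    parent = _grow_tree(n_reaches, p.branch_prob, rng)
    lengths = np.clip(
        rng.normal(p.mean_length, p.length_sd, n_reaches), *p.length_range
    )
    slopes = rng.uniform(*p.slope_range, n_reaches)
    geoms = _layout(parent, lengths, rng)

    reaches = [
        Reach(
            id=f"r{i:04d}",
            length=float(lengths[i]),
            downstream_id=None if parent[i] is None else f"r{parent[i]:04d}",
            longitudinal_slope=float(slopes[i]),
            geometry=geoms[i],
        )
        for i in range(n_reaches)
    ]
    network = ReachNetwork(reaches)
    compute_strahler(network)
    max_order = max(r.strahler_order for r in network)
    lookup = dict(p.geometry_lookup)
    for k in range(1, max_order + 1):
        if k not in lookup:
            lookup.update(default_geometry_lookup(max_order))
            break
    assign_geometry_by_strahler(network, lookup)

    # drainage areas: local increment per reach, accumulated downstream
    local = rng.lognormal(
        math.log(p.local_area_m2) - 0.125, 0.5, n_reaches
    )
    up = network.upstream_map()
    for rid in network.topological_order():
        r = network[rid]
        i = int(rid[1:])
        r.drainage_area = float(local[i]) + sum(
            network[u].drainage_area for u in up[rid]
        )

    # orchards flanking a random subset of reaches
    n_orch = int(round(p.orchard_fraction * n_reaches))
    orch_reaches = rng.choice(n_reaches, size=n_orch, replace=False) if n_orch else []
    orchards = []
    for k, i in enumerate(sorted(orch_reaches)):
        dist = rng.uniform(*p.orchard_distance_range)
        side = 1.0 if rng.random() < 0.5 else -1.0
        poly = _orchard_polygon(geoms[i], dist, side, p.orchard_along_m,
                                p.orchard_across_m)
        orchards.append(Orchard(id=f"o{k:04d}", polygon=poly))

    # forcing series over the full simulation period
    period = p.period
    start = pd.Timestamp(period.start_year, 1, 1)
    end = pd.Timestamp(period.start_year + period.total_years - 1, 12, 31, 23)
    hours = pd.date_range(start, end, freq="h")
    area_km2 = network.outlet.drainage_area / 1e6
    mean_q_m3h = p.specific_discharge * area_km2 * 3.6  # L/s/km2 * km2 -> m3/h
    discharge = _outlet_discharge(hours, mean_q_m3h, p, rng)

    days = pd.date_range(start.normalize(), end.normalize(), freq="D")
    doy = days.dayofyear.to_numpy(float)
    temp_raw = pd.Series(
        p.temp_mean
        + p.temp_amplitude * np.cos(2.0 * math.pi * (doy - p.temp_peak_doy) / 365.25)
        + rng.normal(0.0, p.temp_noise_sd, len(days)),
        index=days,
        name="temperature_c",
    )

    bundle = ScenarioBundle(
        network=network,
        orchards=orchards,
        wind_rose=p.wind_rose,
        substance=p.substance,
        application=p.application,
        period=period,
        discharge=discharge,
        temperature=preprocess_temperature(temp_raw),
        temperature_raw=temp_raw,
        geometry_lookup=lookup,
    )
    bundle.validate()
    return bundle
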