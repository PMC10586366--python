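"""Landscape scenario data model: river network, orchards, wind rose,
substance and application configuration, plus loaders and serializers.

A scenario directory is the on-disk exchange format::

    scenario/
      network.geojson     LineString features, one per reach, with hydraulic
                          attributes in ``properties``
    orchards.geojson      Polygon features (crop label in properties)
      discharge.csv       timestamp (ISO-8601, hourly), discharge_m3_per_s
      temperature.csv     date (ISO-8601, daily), temperature_c  (raw values;
                          the 3-day trailing mean is applied on load)
      windrose.csv        bin_start_deg, bin_end_deg, probability
      config.yaml         substance / application / period / geometry lookup

All coordinates are planar metres (projected CRS); distances, buffer widths
and drift distances are metric throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString, Polygon, mapping, shape

from .errors import ConfigurationError, SchemaError, TopologyError

__all__ = [
    "Reach",
    "ReachNetwork",
    "Orchard",
    "WindRose",
    "SubstanceProperties",
    "ApplicationSetup",
    "SimulationPeriod",
    "GeometrySpec",
    "ScenarioBundle",
    "compute_strahler",
    "assign_geometry_by_strahler",
    "preprocess_temperature",
    "load_scenario",
    "save_scenario",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Reach:
    """A single stream segment (the spatial unit of the whole model).

    Cross sections are trapezoidal: ``bottom_width`` b (m), ``bank_slope`` s
    (horizontal run per unit rise; 0 means rectangular), so the wetted area
    at depth d is ``A = d (b + s d)``.  ``drift_surface_width`` is the water
    surface width assumed to intercept spray drift.
    """

    id: str
    length: float                       # m
    downstream_id: str | None = None    # None marks the outlet
    bottom_width: float = 1.0           # m
    bank_slope: float = 1.0             # run per rise, dimensionless
    manning_n: float = 0.035            # s m^(-1/3)
    longitudinal_slope: float = 0.005   # m/m
    strahler_order: int | None = None
    drainage_area: float = 0.0          # m^2 contributing area
    drift_surface_width: float = 1.0    # m
    geometry: LineString | None = None

    def validate(self) -> None:
        if self.length <= 0:
            raise SchemaError(f"reach {self.id}: length must be > 0")
        if self.manning_n <= 0:
            raise SchemaError(f"reach {self.id}: manning_n must be > 0")
        if self.longitudinal_slope <= 0:
            raise SchemaError(f"reach {self.id}: longitudinal_slope must be > 0")
        if self.bank_slope < 0:
            raise SchemaError(f"reach {self.id}: bank_slope must be >= 0")


class ReachNetwork:
    """Directed river network oriented to a single outlet.

    The topology is a tree (each reach has at most one downstream
    neighbour); construction validates acyclicity, reference resolution and
    the single-outlet invariant.
    """

    def __init__(self, reaches: list[Reach]):
        self._reaches: dict[str, Reach] = {}
        for r in reaches:
            if r.id in self._reaches:
                raise SchemaError(f"duplicate reach id {r.id!r}")
            r.validate()
            self._reaches[r.id] = r
        self._validate_topology()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._reaches)

    def __iter__(self):
        return iter(self._reaches.values())

    def __getitem__(self, reach_id: str) -> Reach:
        return self._reaches[reach_id]

    def __contains__(self, reach_id: str) -> bool:
        return reach_id in self._reaches

    @property
    def reach_ids(self) -> list[str]:
        return list(self._reaches)

    # -- topology ------------------------------------------------------------
    def _validate_topology(self) -> None:
        outlets = [r.id for r in self if r.downstream_id is None]
        if len(outlets) != 1:
            raise TopologyError(
                f"network must have exactly one outlet, found {len(outlets)}"
            )
        for r in self:
            if r.downstream_id is not None and r.downstream_id not in self:
                raise TopologyError(
                    f"reach {r.id}: downstream_id {r.downstream_id!r} does not resolve"
                )
        g = self.to_digraph()
        if not nx.is_directed_acyclic_graph(g):
            raise TopologyError("network topology contains a cycle")

    def to_digraph(self) -> nx.DiGraph:
        """Directed graph with edges pointing downstream."""
        g = nx.DiGraph()
        g.add_nodes_from(self._reaches)
        for r in self:
            if r.downstream_id is not None:
                g.add_edge(r.id, r.downstream_id)
        return g

    @property
    def outlet(self) -> Reach:
        return next(r for r in self if r.downstream_id is None)

    def upstream_map(self) -> dict[str, list[str]]:
        up: dict[str, list[str]] = {rid: [] for rid in self._reaches}
        for r in self:
            if r.downstream_id is not None:
                up[r.downstream_id].append(r.id)
        return up

    def topological_order(self) -> list[str]:
        """Reach ids sorted headwaters-first (every reach after all of its
        upstream neighbours)."""
        return list(nx.topological_sort(self.to_digraph()))

    def validate_drainage_monotone(self) -> None:
        for r in self:
            if r.downstream_id is not None:
                if self[r.downstream_id].drainage_area < r.drainage_area - 1e-6:
                    raise TopologyError(
                        f"drainage_area decreases downstream of reach {r.id}"
                    )

    # -- (de)serialization ---------------------------------------------------
    def to_geojson(self) -> dict:
        feats = []
        for r in self:
            props = {
                "id": r.id,
                "length_m": r.length,
                "downstream_id": r.downstream_id,
                "bottom_width_m": r.bottom_width,
                "bank_slope": r.bank_slope,
                "manning_n": r.manning_n,
                "longitudinal_slope": r.longitudinal_slope,
                "strahler_order": r.strahler_order,
                "drainage_area_m2": r.drainage_area,
                "drift_surface_width_m": r.drift_surface_width,
            }
            geom = mapping(r.geometry) if r.geometry is not None else None
            feats.append({"type": "Feature", "geometry": geom, "properties": props})
        return {"type": "FeatureCollection", "features": feats}

    @classmethod
    def from_geojson(cls, obj: dict) -> "ReachNetwork":
        reaches = []
        for feat in obj.get("features", []):
            p = feat.get("properties", {})
            for key in ("id", "length_m"):
                if key not in p or p[key] is None:
                    raise SchemaError(f"network feature missing field {key!r}")
            geom = shape(feat["geometry"]) if feat.get("geometry") else None
            reaches.append(
                Reach(
                    id=str(p["id"]),
                    length=float(p["length_m"]),
                    downstream_id=(None if p.get("downstream_id") in (None, "")
                                   else str(p["downstream_id"])),
                    bottom_width=float(p.get("bottom_width_m", 1.0)),
                    bank_slope=float(p.get("bank_slope", 1.0)),
                    manning_n=float(p.get("manning_n", 0.035)),
                    longitudinal_slope=float(p.get("longitudinal_slope", 0.005)),
                    strahler_order=(None if p.get("strahler_order") is None
                                    else int(p["strahler_order"])),
                    drainage_area=float(p.get("drainage_area_m2", 0.0)),
                    drift_surface_width=float(p.get("drift_surface_width_m", 1.0)),
                    geometry=geom,
                )
            )
        return cls(reaches)


@dataclass
class Orchard:
    """A treated crop polygon (pome fruit by default)."""

    id: str
    polygon: Polygon
    crop: str = "pome_fruit"

    def validate(self) -> None:
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise SchemaError(f"orchard {self.id}: polygon must have positive area")
        if not self.polygon.is_simple:
            raise SchemaError(f"orchard {self.id}: polygon must be simple")


@dataclass
class WindRose:
    """Discrete wind-direction distribution.

    ``bin_edges`` are compass degrees of the direction the wind blows FROM,
    length n+1, partitioning [0, 360); ``probabilities`` has length n and
    sums to one.
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.validate()

    def validate(self) -> None:
        e, p = self.bin_edges, self.probabilities
        if e.ndim != 1 or p.ndim != 1 or len(e) != len(p) + 1:
            raise SchemaError("wind rose: need n+1 bin edges for n probabilities")
        if not (e[0] == 0.0 and abs(e[-1] - 360.0) < 1e-9):
            raise SchemaError("wind rose bins must partition [0, 360)")
        if np.any(np.diff(e) <= 0):
            raise SchemaError("wind rose bin edges must be strictly increasing")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise SchemaError("wind rose probabilities must be >= 0 and sum to 1")

    def sample(self, rng: np.random.Generator) -> float:
        """Draw a wind-from direction: bin by probability, uniform within bin."""
        i = rng.choice(len(self.probabilities), p=self.probabilities)
        return float(rng.uniform(self.bin_edges[i], self.bin_edges[i + 1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_deg": self.bin_edges[:-1],
                "bin_end_deg": self.bin_edges[1:],
                "probability": self.probabilities,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WindRose":
        for col in ("bin_start_deg", "bin_end_deg", "probability"):
            if col not in df.columns:
                raise SchemaError(f"wind rose table missing column {col!r}")
        starts = df["bin_start_deg"].to_numpy(float)
        ends = df["bin_end_deg"].to_numpy(float)
        if not np.allclose(starts[1:], ends[:-1]):
            raise SchemaError("wind rose bins must be contiguous")
        edges = np.append(starts, ends[-1])
        return cls(edges, df["probability"].to_numpy(float))


@dataclass
class SubstanceProperties:
    """Physico-chemical substance properties.

    Defaults describe a strongly sorbing, non-volatile pyrethroid-like
    insecticide: Koc 1.024e6 L/kg, water/sediment transformation half-lives
    of 1000 d and 43.9 d at 20 degC.  The sediment and suspended-solids
    system parameters are illustrative defaults, configurable per run.
    """

    name: str = "pyrethroid"
    koc: float = 1.024e6                  # L/kg organic carbon
    dt50_water: float = 1000.0            # d at ref_temp
    dt50_sediment: float = 43.9           # d at ref_temp
    ref_temp: float = 20.0                # degC
    molar_activation_energy: float = 65.4  # kJ/mol (Arrhenius correction)
    volatilization_rate: float = 0.0      # 1/d first-order loss from water
    sed_exchange_velocity: float = 0.01   # m/d water-sediment diffusive exchange
    foc_suspended: float = 0.1            # fraction organic carbon
    foc_sediment: float = 0.05
    suspended_solids: float = 1.5e-5      # kg/L (15 mg/L)
    sediment_depth: float = 0.05          # m, single well-mixed layer
    sediment_porosity: float = 0.6        # fraction
    sediment_bulk_density: float = 0.8    # kg dry solids per L bulk volume

    def validate(self) -> None:
        positive = (
            "koc dt50_water dt50_sediment sed_exchange_velocity foc_suspended "
            "foc_sediment sediment_depth sediment_porosity sediment_bulk_density"
        ).split()
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"substance.{name} must be > 0")
        if self.suspended_solids < 0 or self.volatilization_rate < 0:
            raise ConfigurationError(
                "substance.suspended_solids and volatilization_rate must be >= 0"
            )
        for name in ("dt50_water", "dt50_sediment"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"substance.{name} must be finite")


@dataclass
class ApplicationSetup:
    """Annual spray application configuration.

    The window is an annual calendar interval given as ``"MM-DD"`` strings;
    applications happen at ``application_hour`` (noon by default) on a date
    drawn uniformly in the window per orchard and year.
    """

    window_start: str = "04-20"
    window_end: str = "04-30"
    rate: float = 12.5            # g a.i. / ha
    drift_reduction: float = 0.75  # fraction [0, 1]
    buffer_width: float = 10.0    # m minimum effective drift distance
    application_hour: int = 12

    def validate(self) -> None:
        if self.rate <= 0:
            raise ConfigurationError("application rate must be > 0")
        if not 0.0 <= self.drift_reduction <= 1.0:
            raise ConfigurationError("drift_reduction must be in [0, 1]")
        s, e = self.window_doy(2001), self.window_end_doy(2001)
        if s > e:
            raise ConfigurationError("application window_start must be <= window_end")

    def window_doy(self, year: int) -> int:
        m, d = map(int, self.window_start.split("-"))
        return pd.Timestamp(year, m, d).dayofyear

    def window_end_doy(self, year: int) -> int:
        m, d = map(int, self.window_end.split("-"))
        return pd.Timestamp(year, m, d).dayofyear

    def window_dates(self, year: int) -> pd.DatetimeIndex:
        m0, d0 = map(int, self.window_start.split("-"))
        m1, d1 = map(int, self.window_end.split("-"))
        return pd.date_range(pd.Timestamp(year, m0, d0), pd.Timestamp(year, m1, d1))


@dataclass
class SimulationPeriod:
    """Warm-up years are simulated but excluded from all risk end points."""

    warmup_years: int = 6
    assessment_years: int = 20
    start_year: int = 1992

    def validate(self) -> None:
        if self.warmup_years < 0:
            raise ConfigurationError("warmup_years must be >= 0")
        if self.assessment_years < 1:
            raise ConfigurationError("assessment_years must be >= 1")

    @property
    def total_years(self) -> int:
        return self.warmup_years + self.assessment_years

    @property
    def years(self) -> range:
        return range(self.start_year, self.start_year + self.total_years)

    @property
    def assessment_year_list(self) -> list[int]:
        return list(self.years)[self.warmup_years:]


@dataclass
class GeometrySpec:
    """Hydraulic attributes assigned to all reaches of one Strahler order."""

    bottom_width: float
    bank_slope: float
    manning_n: float
    drift_surface_width: float


@dataclass
class ScenarioBundle:
    """Everything one simulation needs, cross-validated.

    ``temperature`` is the preprocessed daily series (trailing mean of the
    three preceding days); ``temperature_raw`` keeps the original input.
    ``discharge`` is the hourly outlet series in m3/h.
    """

    network: ReachNetwork
    orchards: list[Orchard]
    wind_rose: WindRose
    substance: SubstanceProperties
    application: ApplicationSetup
    period: SimulationPeriod
    discharge: pd.Series
    temperature: pd.Series
    temperature_raw: pd.Series | None = None
    geometry_lookup: dict[int, GeometrySpec] | None = None

    def validate(self) -> None:
        self.substance.validate()
        self.application.validate()
        self.period.validate()
        for o in self.orchards:
            o.validate()
        self.network.validate_drainage_monotone()
        if self.network.outlet.drainage_area <= 0:
            raise ConfigurationError("outlet drainage_area must be > 0")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_strahler(network: ReachNetwork) -> ReachNetwork:
    """Assign classical Strahler stream orders in place (and return the
    network).

    Headwater reaches get order 1.  At a junction the order increments only
    when two or more tributaries share the maximum order; otherwise the
    maximum propagates.  A reach with a single upstream neighbour keeps that
    neighbour's order.
    """
    up = network.upstream_map()
    for rid in network.topological_order():
        ups = up[rid]
        if not ups:
            network[rid].strahler_order = 1
            continue
        orders = [network[u].strahler_order for u in ups]
        top = max(orders)
        network[rid].strahler_order = top + 1 if orders.count(top) >= 2 else top
    return network


def assign_geometry_by_strahler(
    network: ReachNetwork, lookup: dict[int, GeometrySpec]
) -> ReachNetwork:
    """Set per-reach hydraulic attributes from a Strahler-order lookup.

    Lengths are never touched.  Raises ``ConfigurationError`` if an order
    present in the network is missing from the lookup.
    """
    present = {r.strahler_order for r in network}
    if None in present:
        raise ConfigurationError("assign_geometry_by_strahler: run compute_strahler first")
    missing = sorted(present - set(lookup))
    if missing:
        raise ConfigurationError(
            f"geometry lookup missing Strahler order(s) {missing}"
        )
    for r in network:
        spec = lookup[r.strahler_order]
        r.bottom_width = spec.bottom_width
        r.bank_slope = spec.bank_slope
        r.manning_n = spec.manning_n
        r.drift_surface_width = spec.drift_surface_width
    return network


def preprocess_temperature(raw: pd.Series) -> pd.Series:
    """Trailing mean of the three *preceding* days.

    Day i gets the mean of days i-3..i-1.  The first three days, which have
    no complete window, are padded with the first computed mean (any
    artefact is absorbed by the warm-up period).
    """
    if len(raw) == 0:
        return raw.copy()
    vals = raw.to_numpy(float)
    out = np.empty_like(vals)
    if len(vals) <= 3:
        out[:] = vals.mean()
    else:
        means = (vals[:-3] + vals[1:-2] + vals[2:-1]) / 3.0
        out[3:] = means
        out[:3] = means[0]
    return pd.Series(out, index=raw.index, name="temperature_c")


def orchard_reach_distance(orchard: Orchard, reach: Reach) -> float:
    """Drift distance between an orchard edge and a reach water surface.

    Minimum Euclidean distance from the orchard polygon to the reach
    centreline, minus half the assumed drift surface width, floored at 0.
    """
    if reach.geometry is None:
        raise ConfigurationError(f"reach {reach.id} has no geometry")
    d = orchard.polygon.distance(reach.geometry) - 0.5 * reach.drift_surface_width
    return max(0.0, d)


# ---------------------------------------------------------------------------
# scenario directory I/O
# ---------------------------------------------------------------------------

_CONFIG_KEYS = ("substance", "application", "period")


def save_scenario(bundle: ScenarioBundle, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    (directory / "network.geojson").write_text(
        json.dumps(bundle.network.to_geojson(), indent=1, sort_keys=True)
    )
    orch_feats = [
        {
            "type": "Feature",
            "geometry": mapping(o.polygon),
            "properties": {"id": o.id, "crop": o.crop},
        }
        for o in bundle.orchards
    ]
    (directory / "orchards.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": orch_feats},
                   indent=1, sort_keys=True)
    )

    q = bundle.discharge / 3600.0  # stored in m3/s per the interface contract
    pd.DataFrame({"timestamp": q.index, "discharge_m3_per_s": q.to_numpy()}).to_csv(
        directory / "discharge.csv", index=False
    )
    traw = bundle.temperature_raw if bundle.temperature_raw is not None else bundle.temperature
    pd.DataFrame(
        {"date": traw.index.strftime("%Y-%m-%d"), "temperature_c": traw.to_numpy()}
    ).to_csv(directory / "temperature.csv", index=False)
    bundle.wind_rose.to_frame().to_csv(directory / "windrose.csv", index=False)

    cfg: dict = {
        "substance": asdict(bundle.substance),
        "application": asdict(bundle.application),
        "period": asdict(bundle.period),
    }
    if bundle.geometry_lookup:
        cfg["geometry_by_strahler"] = {
            int(k): asdict(v) for k, v in bundle.geometry_lookup.items()
        }
    (directory / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return directory


def load_scenario(directory: str | Path) -> ScenarioBundle:
    """Load and validate a scenario directory (see module docstring for the
    layout).  Raises ``SchemaError`` / ``TopologyError`` on bad inputs."""
    directory = Path(directory)
    for name in ("network.geojson", "orchards.geojson", "discharge.csv",
                 "temperature.csv", "windrose.csv", "config.yaml"):
        if not (directory / name).exists():
            raise SchemaError(f"scenario directory missing {name}")

    network = ReachNetwork.from_geojson(
        json.loads((directory / "network.geojson").read_text())
    )
    orchards = []
    for feat in json.loads((directory / "orchards.geojson").read_text())["features"]:
        p = feat.get("properties", {})
        if "id" not in p:
            raise SchemaError("orchard feature missing field 'id'")
        orchards.append(
            Orchard(id=str(p["id"]), polygon=shape(feat["geometry"]),
                    crop=p.get("crop", "pome_fruit"))
        )

    qdf = pd.read_csv(directory / "discharge.csv", parse_dates=["timestamp"])
    if "discharge_m3_per_s" not in qdf.columns:
        raise SchemaError("discharge.csv missing column 'discharge_m3_per_s'")
    discharge = pd.Series(
        qdf["discharge_m3_per_s"].to_numpy(float) * 3600.0,
        index=pd.DatetimeIndex(qdf["timestamp"]),
        name="discharge_m3_per_h",
    )

    tdf = pd.read_csv(directory / "temperature.csv", parse_dates=["date"])
    if "temperature_c" not in tdf.columns:
        raise SchemaError("temperature.csv missing column 'temperature_c'")
    temperature_raw = pd.Series(
        tdf["temperature_c"].to_numpy(float),
        index=pd.DatetimeIndex(tdf["date"]),
        name="temperature_c",
    )

    wind_rose = WindRose.from_frame(pd.read_csv(directory / "windrose.csv"))

    cfg = yaml.safe_load((directory / "config.yaml").read_text()) or {}
    for key in _CONFIG_KEYS:
        if key not in cfg:
            raise SchemaError(f"config.yaml missing section {key!r}")
    substance = SubstanceProperties(**cfg["substance"])
    application = ApplicationSetup(**cfg["application"])
    period = SimulationPeriod(**cfg["period"])
    lookup = None
    if "geometry_by_strahler" in cfg:
        lookup = {
            int(k): GeometrySpec(**v)
            for k, v in cfg["geometry_by_strahler"].items()
        }

    bundle = ScenarioBundle(
        network=network,
        orchards=orchards,
        wind_rose=wind_rose,
        substance=substance,
        application=application,
        period=period,
        discharge=discharge,
        temperature=preprocess_temperature(temperature_raw),
        temperature_raw=temperature_raw,
        geometry_lookup=lookup,
    )
    bundle.validate()
    return bundle
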