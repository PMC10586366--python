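"""End-to-end runner: configuration, seeding, the consecutive component
chain, and the run-directory data store.

The chain mirrors the physical causality: application & drift -> fate ->
effects -> risk end points, with hydrology as external forcing.  Every
stage reads its inputs from the run directory ("the store") and writes
its products back there — there is no direct in-memory hand-off between
stages — so any stage can be re-run in isolation and deleting an
intermediate product and re-running from that stage reproduces identical
downstream outputs.

Store layout::

    <run_dir>/
      manifest.json                 config echo, hash, seed, versions, timings
      scenario/                     scenario directory (see scenario module)
      hydrology/hydro.npz
      drift/deposition.csv
      fate/concentrations.npz       assessment-period exposure field
      fate/ledger.json              mass balance over the full run
      effects/lp50.csv
      risk/report.json, pec_max.csv, categories_<species>_<variant>.csv

Randomness: the master seed spawns one named child stream per stochastic
component (scenario generator, application dates, wind), so regenerating
e.g. only the wind draws leaves the other streams untouched.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .drift import DEFAULT_SECTOR_HALF_ANGLE, DriftCurve, generate_drift_series
from .effects import GutsParams, LP50_CUTOFF, illustrative_species, run_effects
from .endpoints import (
    CONC_FLOOR,
    build_rank_matrix,
    categorize_lp50,
    lp50_pivot,
    overall_percentile,
    pec_max,
)
from .errors import AquariskError, ConfigurationError
from .fate import ConcentrationField, MassLedger, route_network
from .hydrology import HydroSeries, build_hydro_series
from .scenario import (
    ApplicationSetup,
    ScenarioBundle,
    SimulationPeriod,
    SubstanceProperties,
    load_scenario,
    save_scenario,
)
from .synthetic import SyntheticParams, generate_synthetic_catchment

__all__ = ["RunConfig", "run_pipeline", "run_effects_stage", "run_risk_stage"]

log = logging.getLogger(__name__)

_STREAM_NAMES = ("generator", "application_dates", "wind")


@dataclass
class RunConfig:
    """Validated run configuration (see :func:`RunConfig.from_yaml`)."""

    seed: int
    output_dir: Path
    scenario_path: Path | None = None
    n_reaches: int = 100
    synthetic: SyntheticParams = field(default_factory=SyntheticParams)
    species: dict[str, dict[str, GutsParams]] = field(default_factory=illustrative_species)
    curve: DriftCurve = field(default_factory=DriftCurve)
    sector_half_angle: float = DEFAULT_SECTOR_HALF_ANGLE
    conc_floor: float = CONC_FLOOR
    lp50_cutoff: float = LP50_CUTOFF
    figures: bool = False

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")
        for name, variants in self.species.items():
            for variant in ("SD", "IT"):
                if variant not in variants:
                    raise ConfigurationError(
                        f"species {name!r} missing {variant} parameters"
                    )

    # -- construction from YAML ---------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None,
                  output_dir: str | Path | None = None) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw, seed=seed, output_dir=output_dir)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None,
                  output_dir: str | Path | None = None) -> "RunConfig":
        if seed is None:
            if "seed" not in raw:
                raise ConfigurationError("config must specify a seed")
            seed = int(raw["seed"])
        out = Path(output_dir if output_dir is not None
                   else raw.get("output", "aquarisk_run"))

        scen = raw.get("scenario", {}) or {}
        scenario_path = Path(scen["path"]) if "path" in scen else None
        n_reaches = int(scen.get("n_reaches", 100))
        synth = SyntheticParams()
        for key, val in (scen.get("generator", {}) or {}).items():
            if not hasattr(synth, key):
                raise ConfigurationError(f"unknown generator parameter {key!r}")
            setattr(synth, key, val)
        if "substance" in raw:
            synth.substance = SubstanceProperties(**raw["substance"])
        if "application" in raw:
            synth.application = ApplicationSetup(**raw["application"])
        if "period" in raw:
            synth.period = SimulationPeriod(**raw["period"])

        species = illustrative_species()
        if "species" in raw:
            species = {}
            for name, p in raw["species"].items():
                species[name] = {
                    "SD": GutsParams("SD", kd=p["kd"], hb=p.get("hb", 0.0),
                                     b=p["b"], z=p["z"]),
                    "IT": GutsParams("IT", kd=p["kd"], hb=p.get("hb", 0.0),
                                     mw=p["mw"], beta=p["beta"]),
                }

        dr = raw.get("drift", {}) or {}
        curve = DriftCurve(
            coefficient_a=float(dr.get("curve_a", DriftCurve.coefficient_a)),
            exponent_b=float(dr.get("curve_b", DriftCurve.exponent_b)),
            valid_range=tuple(dr.get("valid_range", DriftCurve.valid_range)),
        )
        cut = raw.get("cutoffs", {}) or {}
        cfg = cls(
            seed=seed,
            output_dir=out,
            scenario_path=scenario_path,
            n_reaches=n_reaches,
            synthetic=synth,
            species=species,
            curve=curve,
            sector_half_angle=float(dr.get("sector_half_angle",
                                           DEFAULT_SECTOR_HALF_ANGLE)),
            conc_floor=float(cut.get("concentration_floor", CONC_FLOOR)),
            lp50_cutoff=float(cut.get("lp50_cutoff", LP50_CUTOFF)),
            figures=bool(raw.get("figures", False)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_canonical(cls, d: dict, output_dir: str | Path) -> "RunConfig":
        """Rebuild a config from the canonical form stored in a run
        manifest (inverse of :meth:`canonical_dict`)."""
        from .scenario import GeometrySpec, WindRose

        sd = dict(d["synthetic"])
        synth = SyntheticParams(
            substance=SubstanceProperties(**sd.pop("substance")),
            application=ApplicationSetup(**sd.pop("application")),
            period=SimulationPeriod(**sd.pop("period")),
            geometry_lookup={
                int(k): GeometrySpec(**v)
                for k, v in sd.pop("geometry_lookup").items()
            },
            wind_rose=WindRose(
                np.asarray(sd.pop("wind_rose")["bin_edges"], float),
                np.asarray(d["synthetic"]["wind_rose"]["probabilities"], float),
            ),
            **{k: (tuple(v) if isinstance(v, list) else v) for k, v in sd.items()},
        )
        species = {
            name: {v: GutsParams(**p) for v, p in variants.items()}
            for name, variants in d["species"].items()
        }
        curve_d = dict(d["curve"])
        curve_d["valid_range"] = tuple(curve_d["valid_range"])
        cfg = cls(
            seed=int(d["seed"]),
            output_dir=Path(output_dir),
            scenario_path=Path(d["scenario_path"]) if d.get("scenario_path") else None,
            n_reaches=int(d["n_reaches"]),
            synthetic=synth,
            species=species,
            curve=DriftCurve(**curve_d),
            sector_half_angle=float(d["sector_half_angle"]),
            conc_floor=float(d["conc_floor"]),
            lp50_cutoff=float(d["lp50_cutoff"]),
        )
        cfg.validate()
        return cfg

    def canonical_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "scenario_path": str(self.scenario_path) if self.scenario_path else None,
            "n_reaches": self.n_reaches,
            "synthetic": _jsonable(asdict(self.synthetic)),
            "species": {
                name: {v: asdict(p) for v, p in variants.items()}
                for name, variants in self.species.items()
            },
            "curve": asdict(self.curve),
            "sector_half_angle": self.sector_half_angle,
            "conc_floor": self.conc_floor,
            "lp50_cutoff": self.lp50_cutoff,
        }
        return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "__dict__") and not isinstance(obj, (str, int, float, bool)):
        try:
            return _jsonable(vars(obj))
        except TypeError:
            return str(obj)
    return obj


def _component_seed(master_seed: int, stream: str) -> int:
    """Stable per-component integer seed below 2**31."""
    idx = _STREAM_NAMES.index(stream)
    child = np.random.SeedSequence(master_seed).spawn(len(_STREAM_NAMES))[idx]
    return int(child.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# stages (each reads from and writes to the store only)
# ---------------------------------------------------------------------------

def _stage_scenario(cfg: RunConfig, store: Path) -> None:
    if cfg.scenario_path is not None:
        bundle = load_scenario(cfg.scenario_path)
    else:
        bundle = generate_synthetic_catchment(
            cfg.n_reaches, _component_seed(cfg.seed, "generator"), cfg.synthetic
        )
    save_scenario(bundle, store / "scenario")


def _stage_hydrology(cfg: RunConfig, store: Path) -> None:
    bundle = load_scenario(store / "scenario")
    hydro = build_hydro_series(bundle.network, bundle.discharge)
    (store / "hydrology").mkdir(exist_ok=True)
    hydro.save_npz(store / "hydrology" / "hydro.npz")


def _stage_drift(cfg: RunConfig, store: Path) -> None:
    bundle = load_scenario(store / "scenario")
    rng_dates = np.random.default_rng(_component_seed(cfg.seed, "application_dates"))
    rng_wind = np.random.default_rng(_component_seed(cfg.seed, "wind"))
    df = generate_drift_series(
        bundle, rng_dates, curve=cfg.curve,
        sector_half_angle=cfg.sector_half_angle, rng_wind=rng_wind,
    )
    (store / "drift").mkdir(exist_ok=True)
    df.to_csv(store / "drift" / "deposition.csv", index=False)


def _stage_fate(cfg: RunConfig, store: Path) -> None:
    bundle = load_scenario(store / "scenario")
    hydro = HydroSeries.load_npz(store / "hydrology" / "hydro.npz")
    drift = pd.read_csv(store / "drift" / "deposition.csv",
                        parse_dates=["timestamp"])
    field, ledger = route_network(
        bundle.network, hydro, drift, bundle.substance,
        bundle.temperature, period=bundle.period,
    )
    ledger.validate(tol=1e-6)
    (store / "fate").mkdir(exist_ok=True)
    field.save_npz(store / "fate" / "concentrations.npz")
    ledger.to_json(store / "fate" / "ledger.json")
    log.info("mass ledger: input %.4g ug, closure error %.2e",
             ledger.input, ledger.closure_error())


def run_effects_stage(cfg: RunConfig, store: Path) -> None:
    field = ConcentrationField.load_npz(store / "fate" / "concentrations.npz")
    lp = run_effects(field, cfg.species, cutoff=cfg.lp50_cutoff)
    (store / "effects").mkdir(exist_ok=True)
    out = lp.copy()
    out["lp50"] = out["lp50"].map(lambda v: f"{v:.6g}" if np.isfinite(v) else "")
    out.to_csv(store / "effects" / "lp50.csv", index=False)


def _load_lp50(store: Path) -> pd.DataFrame:
    lp = pd.read_csv(store / "effects" / "lp50.csv",
                     dtype={"lp50": float}, na_values=[""])
    lp["lp50"] = lp["lp50"].fillna(np.inf)
    return lp


def run_risk_stage(cfg: RunConfig, store: Path) -> dict:
    bundle = load_scenario(store / "scenario")
    hydro = HydroSeries.load_npz(store / "hydrology" / "hydro.npz")
    drift = pd.read_csv(store / "drift" / "deposition.csv",
                        parse_dates=["timestamp"])
    field = ConcentrationField.load_npz(store / "fate" / "concentrations.npz")
    ledger = json.loads((store / "fate" / "ledger.json").read_text())
    lp = _load_lp50(store)

    risk_dir = store / "risk"
    risk_dir.mkdir(exist_ok=True)
    network = bundle.network
    period = bundle.period
    years = period.assessment_year_list
    n_reaches = len(network)

    pec = pec_max(field, floor=cfg.conc_floor)
    pec.to_csv(risk_dir / "pec_max.csv", index=False)

    orders = {rid: network[rid].strahler_order for rid in network.reach_ids}
    order_arr = np.array([orders[r] for r in field.reach_ids])
    order_share = {
        int(k): round(100.0 * float((order_arr == k).sum()) / n_reaches, 2)
        for k in sorted(set(order_arr))
    }

    # residence-time medians in the application window, assessment years
    win_frames = [bundle.application.window_dates(y) for y in years]
    win_days = pd.DatetimeIndex(np.concatenate([w.to_numpy() for w in win_frames]))
    app_mask = hydro.index.normalize().isin(win_days)
    rt = hydro.residence_minutes()[np.asarray(app_mask)]
    residence_by_order = {}
    for k in sorted(set(order_arr)):
        sel = rt[:, order_arr == k]
        finite = sel[np.isfinite(sel)]
        residence_by_order[int(k)] = float(np.median(finite)) if len(finite) else None

    mean_annual_dep_mg = float(drift["mass_ug"].sum()) / max(len(years), 1) / 1e6 \
        if len(drift) else 0.0
    directly_dosed = set(drift["reach_id"]) if len(drift) else set()

    ever = field.cw.max(axis=0) > 0.0
    never_pct = round(100.0 * float((~ever).sum()) / n_reaches, 2)
    never_by_order = {
        int(k): round(100.0 * float((~ever[order_arr == k]).sum())
                      / max(int((order_arr == k).sum()), 1), 2)
        for k in sorted(set(order_arr))
    }

    report = {
        "n_reaches": n_reaches,
        "n_orchards": len(bundle.orchards),
        "assessment_years": len(years),
        "strahler_share_pct": order_share,
        "median_residence_app_window_min_by_order": residence_by_order,
        "drift": {
            "mean_annual_deposition_mg": round(mean_annual_dep_mg, 4),
            "directly_dosed_reach_pct": round(
                100.0 * len(directly_dosed) / n_reaches, 2
            ),
        },
        "never_exposed_reach_pct": never_pct,
        "never_exposed_by_order_pct": never_by_order,
        "pec": {
            "overall_p90_ug_per_l": overall_percentile(pec, 90.0),
            "overall_p90_count_ug_per_l": overall_percentile(pec, 90.0, kind="count"),
            "max_ug_per_l": float(pec["pec_max_ug_per_l"].max()),
        },
        "lp50": {},
        "mass_ledger": ledger,
    }

    for sp in sorted({s for s in lp["species"]}):
        report["lp50"][sp] = {}
        for variant in ("IT", "SD"):
            piv = lp50_pivot(lp, sp, variant)
            finite = np.isfinite(piv.to_numpy(float))
            entry = {"finite_reach_year_pct": round(
                100.0 * float(finite.sum()) / finite.size, 2)}
            try:
                entry["overall_p10"] = overall_percentile(
                    lp[(lp.species == sp) & (lp.variant == variant)], 10.0
                )
            except ConfigurationError:
                entry["overall_p10"] = None  # 10th percentile falls on a sentinel
            cats = categorize_lp50(lp, sp, variant)
            cats.to_csv(risk_dir / f"categories_{sp}_{variant}.csv", index=False)
            entry["worst_year_categories"] = (
                cats["category"].value_counts().to_dict()
            )
            report["lp50"][sp][variant] = entry

    (risk_dir / "report.json").write_text(
        json.dumps(_jsonable(report), indent=1, sort_keys=True)
    )
    if cfg.figures:
        _write_figures(store, pec, lp)
    return report


def _write_figures(store: Path, pec: pd.DataFrame, lp: pd.DataFrame) -> None:
    """Optional reporting plots (rank-matrix heat maps)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = store / "risk" / "figures"
    fig_dir.mkdir(exist_ok=True)
    rm = build_rank_matrix(pec, "exposure")
    with np.errstate(divide="ignore"):
        img = np.log10(np.maximum(rm.values, CONC_FLOOR))
    fig, ax = plt.subplots(figsize=(8, 3))
    im = ax.imshow(img, aspect="auto", origin="upper", cmap="viridis")
    ax.set_xlabel("reaches (ranked)")
    ax.set_ylabel("years (ranked)")
    fig.colorbar(im, ax=ax, label="log10 PECmax (ug/L)")
    fig.tight_layout()
    fig.savefig(fig_dir / "pec_rank_matrix.png", dpi=120)
    plt.close(fig)

    sp = sorted(set(lp["species"]))[0]
    piv = lp50_pivot(lp, sp, "IT")
    rm = build_rank_matrix(piv, "effect")
    vals = np.where(np.isfinite(rm.values), rm.values, np.nan)
    fig, ax = plt.subplots(figsize=(8, 3))
    im = ax.imshow(np.log10(vals), aspect="auto", origin="upper", cmap="viridis_r")
    ax.set_xlabel("reaches (ranked)")
    ax.set_ylabel("years (ranked)")
    fig.colorbar(im, ax=ax, label=f"log10 LP50 ({sp}, IT)")
    fig.tight_layout()
    fig.savefig(fig_dir / "lp50_rank_matrix.png", dpi=120)
    plt.close(fig)


_STAGES = (
    ("scenario", _stage_scenario),
    ("hydrology", _stage_hydrology),
    ("drift", _stage_drift),
    ("fate", _stage_fate),
    ("effects", run_effects_stage),
    ("risk", run_risk_stage),
)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full component chain into ``cfg.output_dir``.

    Identical config + seed reproduce byte-identical store contents.  On a
    stage failure the partial store is preserved and the error names the
    stage.
    """
    cfg.validate()
    store = Path(cfg.output_dir)
    store.mkdir(parents=True, exist_ok=True)

    canon = json.dumps(cfg.canonical_dict(), sort_keys=True)
    manifest = {
        "config": cfg.canonical_dict(),
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "seed": cfg.seed,
        "component_seeds": {s: _component_seed(cfg.seed, s) for s in _STREAM_NAMES},
        "version": __version__,
        "stages": {},
    }
    for name, fn in _STAGES:
        t0 = time.perf_counter()
        try:
            fn(cfg, store)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (store / "manifest.json").write_text(
                json.dumps(_jsonable(manifest), indent=1, sort_keys=True))
            raise AquariskError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"status": "ok", "seconds": round(dt, 3)}
        log.info("stage %-9s done in %.1f s", name, dt)
    (store / "manifest.json").write_text(
        json.dumps(_jsonable(manifest), indent=1, sort_keys=True))
    return store
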