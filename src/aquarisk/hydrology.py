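"""Per-reach hourly hydrology from an outlet discharge series.

The catchment-area-yield approach scales the observed (or synthetic) outlet
discharge to every reach in proportion to its contributing drainage area:

    Q_reach(t) = Q_outlet(t) * A_reach / A_outlet

Water depth follows from Manning's equation for a trapezoidal cross
section, solved per reach-hour by bisection (Manning discharge is strictly
monotone in depth, so the bracket [floor, 10 m] is unconditionally safe):

    Q = (1/n) A(d) R(d)^(2/3) sqrt(S),   A = d (b + s d),
    P = b + 2 d sqrt(1 + s^2),           R = A / P

Velocity is Q / A and reach volume is A * length; residence time is the
volume/discharge ratio.  The module can equally ingest precomputed
per-reach series via :meth:`HydroSeries.from_csv`, bypassing the
disaggregation entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericalError
from .scenario import Reach, ReachNetwork

__all__ = [
    "DEFAULT_DEPTH_FLOOR",
    "HydroSeries",
    "disaggregate_discharge",
    "solve_depth_manning",
    "residence_time",
    "build_hydro_series",
]

DEFAULT_DEPTH_FLOOR = 0.01  # m; minimum water depth at zero discharge
_DEPTH_MAX = 10.0           # m; upper bisection bracket
_DEPTH_TOL = 1e-8           # m
_MAX_ITER = 80


@numba.njit(cache=True)
def _manning_q(d, b, s, n, slope):
    area = d * (b + s * d)
    per = b + 2.0 * d * np.sqrt(1.0 + s * s)
    radius = area / per
    return area * radius ** (2.0 / 3.0) * np.sqrt(slope) / n


@numba.njit(cache=True)
def _solve_depth_array(q_m3s, b, s, n, slope, floor):
    """Element-wise bisection for normal depth. q is in m3/s; b, s, n,
    slope broadcast per element."""
    out = np.empty(q_m3s.shape[0])
    for i in range(q_m3s.shape[0]):
        q = q_m3s[i]
        if q <= 0.0:
            out[i] = floor
            continue
        lo, hi = floor, _DEPTH_MAX
        if _manning_q(hi, b[i], s[i], n[i], slope[i]) < q:
            out[i] = np.nan  # discharge above bracket; caller raises
            continue
        if _manning_q(lo, b[i], s[i], n[i], slope[i]) >= q:
            out[i] = lo
            continue
        for _ in range(_MAX_ITER):
            mid = 0.5 * (lo + hi)
            if _manning_q(mid, b[i], s[i], n[i], slope[i]) < q:
                lo = mid
            else:
                hi = mid
            if hi - lo < _DEPTH_TOL:
                break
        out[i] = 0.5 * (lo + hi)
    return out


def solve_depth_manning(
    discharge_m3h: float | np.ndarray,
    reach: Reach,
    floor: float = DEFAULT_DEPTH_FLOOR,
) -> float | np.ndarray:
    """Normal water depth (m) for an hourly discharge (m3/h) in a reach.

    Zero (or negative) discharge returns the configured depth floor.
    Raises :class:`NumericalError` if the discharge exceeds the bracket's
    capacity at 10 m depth.
    """
    q = np.atleast_1d(np.asarray(discharge_m3h, dtype=float)) / 3600.0
    k = len(q)
    d = _solve_depth_array(
        q,
        np.full(k, reach.bottom_width),
        np.full(k, reach.bank_slope),
        np.full(k, reach.manning_n),
        np.full(k, reach.longitudinal_slope),
        floor,
    )
    if np.any(np.isnan(d)):
        raise NumericalError(
            f"reach {reach.id}: discharge exceeds Manning capacity at "
            f"{_DEPTH_MAX} m depth (max Q tried: {q.max() * 3600:.3g} m3/h)"
        )
    if np.isscalar(discharge_m3h) or np.asarray(discharge_m3h).ndim == 0:
        return float(d[0])
    return d


def disaggregate_discharge(
    outlet_series: pd.Series, network: ReachNetwork
) -> pd.DataFrame:
    """Catchment-area-yield scaling of the outlet discharge to all reaches.

    Returns a DataFrame indexed by the outlet series' timestamps with one
    column per reach id (m3/h).
    """
    a_out = network.outlet.drainage_area
    if a_out <= 0:
        raise ConfigurationError("outlet drainage_area must be > 0")
    ratios = np.array([network[rid].drainage_area / a_out for rid in network.reach_ids])
    if np.any(ratios > 1.0 + 1e-9):
        raise ConfigurationError("a reach drainage_area exceeds the outlet's")
    q = np.outer(outlet_series.to_numpy(float), ratios)
    return pd.DataFrame(q, index=outlet_series.index, columns=network.reach_ids)


def residence_time(volume_m3, discharge_m3h):
    """Residence time in minutes: 60 * V / Q.  Q = 0 maps to +inf (the
    'infinite residence' sentinel); V = 0 with positive Q gives 0."""
    v = np.asarray(volume_m3, dtype=float)
    q = np.asarray(discharge_m3h, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rt = np.where(q > 0.0, 60.0 * v / np.maximum(q, 1e-300), np.inf)
    rt = np.where((v == 0.0) & (q > 0.0), 0.0, rt)
    if rt.ndim == 0:
        return float(rt)
    return rt


@dataclass
class HydroSeries:
    """Hourly hydraulic state for every reach.

    Arrays are (n_hours, n_reaches), aligned with ``index`` and
    ``reach_ids``.  Units: discharge m3/h, depth m, velocity m/h,
    volume m3.
    """

    index: pd.DatetimeIndex
    reach_ids: list[str]
    discharge: np.ndarray
    depth: np.ndarray
    velocity: np.ndarray
    volume: np.ndarray

    def column(self, reach_id: str) -> int:
        return self.reach_ids.index(reach_id)

    def residence_minutes(self) -> np.ndarray:
        return residence_time(self.volume, self.discharge)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (one row per reach-hour); the CSV exchange
        layout."""
        n_h, n_r = self.discharge.shape
        return pd.DataFrame(
            {
                "reach_id": np.repeat(self.reach_ids, n_h),
                "timestamp": np.tile(self.index.to_numpy(), n_r),
                "discharge_m3_per_h": self.discharge.T.ravel(),
                "depth_m": self.depth.T.ravel(),
                "velocity_m_per_h": self.velocity.T.ravel(),
                "volume_m3": self.volume.T.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HydroSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        reach_ids = sorted(df["reach_id"].unique())
        index = pd.DatetimeIndex(sorted(df["timestamp"].unique()))
        shape = (len(index), len(reach_ids))
        arrays = {}
        piv = df.pivot(index="timestamp", columns="reach_id")
        for name, col in (
            ("discharge", "discharge_m3_per_h"),
            ("depth", "depth_m"),
            ("velocity", "velocity_m_per_h"),
            ("volume", "volume_m3"),
        ):
            arrays[name] = piv[col].loc[index, reach_ids].to_numpy(float).reshape(shape)
        return cls(index=index, reach_ids=reach_ids, **arrays)

    def save_npz(self, path) -> None:
        """Binary store product.  Arrays are stored at single precision to
        keep multi-decade runs compact; consumers get float64 back."""
        np.savez(
            path,
            index=self.index.asi8,
            reach_ids=np.array(self.reach_ids),
            discharge=self.discharge.astype(np.float32),
            depth=self.depth.astype(np.float32),
            velocity=self.velocity.astype(np.float32),
            volume=self.volume.astype(np.float32),
        )

    @classmethod
    def load_npz(cls, path) -> "HydroSeries":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                index=pd.DatetimeIndex(z["index"].view("datetime64[ns]")),
                reach_ids=[str(x) for x in z["reach_ids"]],
                discharge=z["discharge"].astype(np.float64),
                depth=z["depth"].astype(np.float64),
                velocity=z["velocity"].astype(np.float64),
                volume=z["volume"].astype(np.float64),
            )


def build_hydro_series(
    network: ReachNetwork,
    outlet_series: pd.Series,
    floor: float = DEFAULT_DEPTH_FLOOR,
) -> HydroSeries:
    """Disaggregate the outlet discharge and solve depth/velocity/volume
    for every reach-hour."""
    qdf = disaggregate_discharge(outlet_series, network)
    reach_ids = network.reach_ids
    n_h, n_r = qdf.shape
    q = qdf.to_numpy(float)

    b = np.empty(n_r); s = np.empty(n_r); n_ = np.empty(n_r)
    slope = np.empty(n_r); length = np.empty(n_r)
    for j, rid in enumerate(reach_ids):
        r = network[rid]
        b[j], s[j], n_[j] = r.bottom_width, r.bank_slope, r.manning_n
        slope[j], length[j] = r.longitudinal_slope, r.length

    d = _solve_depth_array(
        (q / 3600.0).ravel(),
        np.broadcast_to(b, (n_h, n_r)).ravel(),
        np.broadcast_to(s, (n_h, n_r)).ravel(),
        np.broadcast_to(n_, (n_h, n_r)).ravel(),
        np.broadcast_to(slope, (n_h, n_r)).ravel(),
        floor,
    ).reshape(n_h, n_r)
    if np.any(np.isnan(d)):
        raise NumericalError("Manning depth solver: discharge above bracket capacity")

    area = d * (b + s * d)
    volume = area * length
    with np.errstate(divide="ignore", invalid="ignore"):
        velocity = np.where(area > 0, q / np.maximum(area, 1e-300), 0.0)
    return HydroSeries(
        index=qdf.index,
        reach_ids=reach_ids,
        discharge=q,
        depth=d,
        velocity=velocity,
        volume=volume,
    )
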