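"""Reduced GUTS survival models (SD and IT) and LP50 margins of safety.

The reduced General Unified Threshold model of Survival uses scaled
damage D(t) as the dose metric, a one-compartment first-order proxy for
the internal exposure:

    dD/dt = kd (C(t) - D),  D(0) = 0

integrated exactly per hour for piecewise-constant exposure C.  Two
toxicodynamic variants share that toxicokinetic core:

* stochastic death (SD): the hazard rate rises linearly with damage above
  a threshold z, h(t) = b max(D - z, 0) + hb, and
  S(t) = exp(-integral of h);
* individual tolerance (IT): each individual carries a fixed threshold
  drawn from a log-logistic population distribution (median mw, shape
  beta); death is immediate on exceedance, so survival depends only on the
  running maximum of the damage:
  S(t) = (1 - F(max D)) exp(-hb t).

The LP50 of a reach-year is the factor f multiplying the entire hourly
exposure profile such that end-of-year survival drops to half of the
unexposed control, S_f(T)/S_0(T) = 1/2 (the division removes the
background hazard hb).  Because the toxicokinetics are linear in C, the
LP50 scales inversely with the exposure profile.  Rates (kd, hb, b) are
per day; concentrations and thresholds in ug/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError, NumericalError
from .fate import ConcentrationField

__all__ = [
    "NO_EXPOSURE",
    "ABOVE_CUTOFF",
    "OK",
    "LP50_CUTOFF",
    "GutsParams",
    "illustrative_species",
    "scaled_damage",
    "survival_sd",
    "survival_it",
    "lp50",
    "run_effects",
]

HOUR_D = 1.0 / 24.0  # hour expressed in days

NO_EXPOSURE = "NO_EXPOSURE"
ABOVE_CUTOFF = "ABOVE_CUTOFF"
OK = "OK"
LP50_CUTOFF = 1e5

_LN2 = math.log(2.0)
_REL_TOL = 1e-4  # relative tolerance of the LP50 bisection
_F_LO = 1e-9     # lower bracket start for the multiplication factor


@dataclass(frozen=True)
class GutsParams:
    """Parameter set of one reduced-GUTS variant for one species.

    variant "SD" requires b (killing rate, L/(ug d)) and z (threshold,
    ug/L); variant "IT" requires mw (median threshold, ug/L) and beta
    (log-logistic shape).  kd (dominant rate constant) and hb (background
    hazard) are shared, both 1/d.
    """

    variant: str
    kd: float
    hb: float = 0.0
    b: float | None = None
    z: float | None = None
    mw: float | None = None
    beta: float | None = None

    def __post_init__(self):
        if self.variant not in ("SD", "IT"):
            raise ConfigurationError("GUTS variant must be 'SD' or 'IT'")
        if self.kd < 0 or self.hb < 0:
            raise ConfigurationError("GUTS rates kd and hb must be >= 0")
        if self.variant == "SD":
            if self.b is None or self.z is None:
                raise ConfigurationError("SD parameters require b and z")
            if self.b < 0 or self.z < 0:
                raise ConfigurationError("SD b and z must be >= 0")
        else:
            if self.mw is None or self.beta is None:
                raise ConfigurationError("IT parameters require mw and beta")
            if self.mw <= 0 or self.beta <= 0:
                raise ConfigurationError("IT mw and beta must be > 0")


def illustrative_species() -> dict[str, dict[str, GutsParams]]:
    """Three illustrative macroinvertebrate parameter sets.

    These are placeholders spanning a plausible sensitivity range for a
    pyrethroid-like insecticide — NOT calibrated values for any real
    species; supply calibrated parameters via run configuration for real
    assessments.
    """
    spec = {
        "isopod_a": dict(kd=0.7, hb=0.005, b=0.6, z=0.15, mw=0.30, beta=2.5),
        "mayfly_b": dict(kd=1.2, hb=0.008, b=1.5, z=0.05, mw=0.12, beta=2.0),
        "amphipod_c": dict(kd=0.9, hb=0.006, b=0.9, z=0.08, mw=0.20, beta=3.0),
    }
    out: dict[str, dict[str, GutsParams]] = {}
    for name, p in spec.items():
        out[name] = {
            "SD": GutsParams("SD", kd=p["kd"], hb=p["hb"], b=p["b"], z=p["z"]),
            "IT": GutsParams("IT", kd=p["kd"], hb=p["hb"], mw=p["mw"], beta=p["beta"]),
        }
    return out


# ---------------------------------------------------------------------------
# toxicokinetics
# ---------------------------------------------------------------------------

def scaled_damage(profile: np.ndarray, kd: float, dt_d: float = HOUR_D) -> np.ndarray:
    """Scaled damage at the step ends of a piecewise-constant profile.

    Exact per-step update D(t+dt) = C + (D - C) exp(-kd dt).  Returns an
    array of length ``len(profile) + 1`` starting at D(0) = 0.
    """
    c = np.asarray(profile, dtype=float)
    n = len(c)
    out = np.empty(n + 1)
    out[0] = 0.0
    if kd == 0.0 or n == 0:
        out[1:] = 0.0
        return out
    beta = math.exp(-kd * dt_d)
    # D[i+1] = beta D[i] + (1-beta) C[i]  -> first-order IIR filter
    out[1:] = lfilter([1.0 - beta], [1.0, -beta], c)
    return out


# ---------------------------------------------------------------------------
# toxicodynamics
# ---------------------------------------------------------------------------

def _times_d(n_steps: int, dt_d: float) -> np.ndarray:
    return np.arange(n_steps + 1) * dt_d


def survival_sd(damage: np.ndarray, params: GutsParams,
                dt_d: float = HOUR_D) -> np.ndarray:
    """Stochastic-death survival on the damage grid (length n+1, S[0]=1)."""
    if params.variant != "SD":
        raise ConfigurationError("survival_sd needs SD parameters")
    d = np.asarray(damage, dtype=float)
    hazard = params.b * np.maximum(d - params.z, 0.0)
    cum = np.concatenate(
        ([0.0], np.cumsum((hazard[1:] + hazard[:-1]) * 0.5 * dt_d))
    )
    t = _times_d(len(d) - 1, dt_d)
    return np.exp(-(cum + params.hb * t))


def survival_it(damage: np.ndarray, params: GutsParams,
                dt_d: float = HOUR_D) -> np.ndarray:
    """Individual-tolerance survival: only the running damage maximum
    matters; F is the log-logistic threshold distribution with F(0)=0."""
    if params.variant != "IT":
        raise ConfigurationError("survival_it needs IT parameters")
    d = np.asarray(damage, dtype=float)
    running = np.maximum.accumulate(d)
    frac = np.zeros_like(running)
    pos = running > 0.0
    # log-logistic CDF via the logistic sigmoid: overflow-free for extreme
    # damage/threshold ratios
    from scipy.special import expit
    frac[pos] = expit(params.beta * np.log(running[pos] / params.mw))
    t = _times_d(len(d) - 1, dt_d)
    return (1.0 - frac) * np.exp(-params.hb * t)


# ---------------------------------------------------------------------------
# LP50
# ---------------------------------------------------------------------------

def _end_ratio(damage_unit: np.ndarray, factor: float, params: GutsParams,
               dt_d: float) -> float:
    """S_f(T)/S_0(T); the background hazard cancels analytically."""
    d = factor * damage_unit
    if params.variant == "SD":
        hazard = params.b * np.maximum(d - params.z, 0.0)
        integral = np.sum((hazard[1:] + hazard[:-1])) * 0.5 * dt_d
        return math.exp(-integral)
    dmax = float(d.max())
    if dmax <= 0.0:
        return 1.0
    return 1.0 / (1.0 + (dmax / params.mw) ** params.beta)


def lp50(
    profile: np.ndarray,
    params: GutsParams,
    cutoff: float = LP50_CUTOFF,
    dt_d: float = HOUR_D,
) -> tuple[float, str]:
    """Multiplication factor halving end-of-window survival vs control.

    Returns ``(value, status)``: status OK with the factor, NO_EXPOSURE
    for an all-zero profile (no factor can produce mortality; the margin
    is infinite), or ABOVE_CUTOFF when the factor exceeds ``cutoff``.

    Bisection on log10(f) to a relative tolerance of 1e-4; the survival
    ratio is monotone non-increasing in f because damage scales linearly
    with the profile.
    """
    c = np.asarray(profile, dtype=float)
    if len(c) == 0 or float(c.max()) <= 0.0:
        return math.inf, NO_EXPOSURE
    damage_unit = scaled_damage(c, params.kd, dt_d)
    if float(damage_unit.max()) <= 0.0:  # kd = 0: no uptake, no effect
        return math.inf, NO_EXPOSURE

    if _end_ratio(damage_unit, cutoff, params, dt_d) > 0.5:
        return math.inf, ABOVE_CUTOFF

    lo = math.log10(_F_LO)
    hi = math.log10(cutoff)
    if _end_ratio(damage_unit, _F_LO, params, dt_d) < 0.5:
        return _F_LO, OK  # profile lethal even at a negligible factor
    # invariant: ratio(10**lo) >= 0.5 >= ratio(10**hi)
    tol_log = math.log10(1.0 + _REL_TOL)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _end_ratio(damage_unit, 10.0 ** mid, params, dt_d) >= 0.5:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol_log:
            break
    else:
        raise NumericalError("LP50 bisection did not converge")
    return 10.0 ** (0.5 * (lo + hi)), OK


# ---------------------------------------------------------------------------
# field-level driver
# ---------------------------------------------------------------------------

def run_effects(
    field: ConcentrationField,
    species: dict[str, dict[str, GutsParams]],
    years: list[int] | None = None,
    cutoff: float = LP50_CUTOFF,
) -> pd.DataFrame:
    """LP50 per reach x year x species x variant.

    Years are treated independently (damage does not carry over across
    New Year).  The field must cover every requested year completely at
    hourly resolution, January 1st to December 31st.

    Returns a long DataFrame with columns reach_id, year, species,
    variant, lp50 (float, inf for sentinels) and status.
    """
    if years is None:
        years = sorted(set(field.index.year))
    rows = []
    year_arr = field.index.year
    for year in years:
        hours = np.nonzero(year_arr == year)[0]
        expected = 8784 if pd.Timestamp(year, 1, 1).is_leap_year else 8760
        if len(hours) != expected:
            raise ConfigurationError(
                f"field does not cover year {year} completely "
                f"({len(hours)} of {expected} hours)"
            )
        block = field.cw[hours]
        for j, rid in enumerate(field.reach_ids):
            profile = block[:, j]
            exposed = float(profile.max()) > 0.0
            for sp_name, variants in species.items():
                if not exposed:
                    for variant in variants:
                        rows.append((rid, year, sp_name, variant,
                                     math.inf, NO_EXPOSURE))
                    continue
                for variant, params in variants.items():
                    value, status = lp50(profile, params, cutoff=cutoff)
                    rows.append((rid, year, sp_name, variant, value, status))
    return pd.DataFrame(
        rows, columns=["reach_id", "year", "species", "variant", "lp50", "status"]
    )
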