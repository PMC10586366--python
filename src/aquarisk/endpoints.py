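"""Landscape-scale risk characterization end points.

Aggregates the exposure field and the LP50 table into the reporting
objects used for landscape risk assessment:

* PECmax — the annual maximum of hourly averaged water concentration per
  reach;
* overall percentiles over all reach-years (e.g. the exposure goal "the
  overall 90th percentile of annual peak concentrations");
* spatiotemporal rank matrices (reach columns x year rows, sorted so the
  worst reach-year sits in the bottom-left corner) and exceedance
  fractions read from them;
* worst-year LP50 category maps (the 5th percentile year of each reach).

Sentinel ordering for risk purposes: finite LP50 < ABOVE_CUTOFF
(effect-free) < NO_EXPOSURE; the two sentinel classes are "no concern"
and rank after every finite margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .effects import ABOVE_CUTOFF, NO_EXPOSURE, OK
from .fate import ConcentrationField

__all__ = [
    "CONC_FLOOR",
    "LP50_BIN_EDGES",
    "RankMatrix",
    "pec_max",
    "overall_percentile",
    "lp50_pivot",
    "build_rank_matrix",
    "fraction_exceeding",
    "categorize_lp50",
]

CONC_FLOOR = 1e-6          # ug/L reporting floor for concentrations
LP50_BIN_EDGES = (1.0, 10.0, 100.0, 1e5)

#: category labels, worst first
CATEGORIES = ("<1", "1-10", "10-100", "100-1e5", "effect-free", "no-exposure")

# sentinel encodings inside float matrices
_EFFECT_FREE = math.inf
_NO_EXPOSURE_RANK = 2.0  # used only in the sentinel mask


def pec_max(field: ConcentrationField, floor: float = CONC_FLOOR) -> pd.DataFrame:
    """Annual maximum of hourly averaged concentration per reach.

    Long DataFrame: reach_id, year, pec_max_ug_per_l, below_floor flag.
    """
    years = sorted(set(field.index.year))
    rows = []
    year_arr = field.index.year
    for year in years:
        hours = np.nonzero(year_arr == year)[0]
        peak = field.cw[hours].max(axis=0)
        for j, rid in enumerate(field.reach_ids):
            rows.append((rid, year, float(peak[j]), bool(peak[j] < floor)))
    return pd.DataFrame(
        rows, columns=["reach_id", "year", "pec_max_ug_per_l", "below_floor"]
    )


def _pool_values(table: pd.DataFrame) -> np.ndarray:
    """Pool reach x year values from a PEC or LP50 long table.

    LP50 sentinels map to +inf (no-concern; worse margins are smaller).
    """
    if "pec_max_ug_per_l" in table.columns:
        return table["pec_max_ug_per_l"].to_numpy(float)
    if "lp50" in table.columns:
        vals = table["lp50"].to_numpy(float).copy()
        if "status" in table.columns:
            vals[(table["status"] != OK).to_numpy()] = math.inf
        return vals
    raise ConfigurationError("table is neither a PEC nor an LP50 table")


def overall_percentile(
    table: pd.DataFrame | np.ndarray, p: float, kind: str = "linear"
) -> float:
    """Percentile over the pooled reach x year values.

    ``kind="linear"`` interpolates between order statistics (numpy's
    default estimator); ``kind="count"`` returns the smallest pooled value
    with at least p% of values at or below it (inverted CDF), matching
    "k out of n years" statements.  Sentinels count as +inf and the
    percentile must land on a finite value.
    """
    vals = _pool_values(table) if isinstance(table, pd.DataFrame) else np.asarray(
        table, dtype=float
    )
    finite = vals[np.isfinite(vals)]
    if len(finite) == 0:
        raise ConfigurationError("overall_percentile: no finite values to pool")
    method = {"linear": "linear", "count": "inverted_cdf"}[kind]
    if np.isinf(vals).any():
        # order statistics on the full pool, inf ranked last
        vals = np.sort(vals)
        q = np.percentile(vals, p, method=method)
    else:
        q = np.percentile(vals, p, method=method)
    if not np.isfinite(q):
        raise ConfigurationError(
            "overall_percentile: requested percentile falls on a sentinel"
        )
    return float(q)


@dataclass
class RankMatrix:
    """Spatiotemporally ranked value grid.

    ``values`` has one column per reach and one row per year, after
    within-column and cross-column sorting; row 0 is the TOP of the plot,
    so the worst reach-year sits at [n_years-1, 0] (bottom-left).
    ``sentinel`` carries 0 = finite, 1 = effect-free (no model fit
    possible / above cutoff), 2 = no exposure.  ``column_reach_ids`` maps
    columns back to reaches.
    """

    values: np.ndarray
    column_reach_ids: list[str]
    sentinel: np.ndarray
    direction: str  # "exposure" | "effect"


def lp50_pivot(lp50_table: pd.DataFrame, species: str, variant: str) -> pd.DataFrame:
    """Years x reaches pivot of one species/variant slice; sentinels as
    +inf (effect-free) and NaN is not used."""
    sub = lp50_table[
        (lp50_table["species"] == species) & (lp50_table["variant"] == variant)
    ].copy()
    sub.loc[sub["status"] != OK, "lp50"] = math.inf
    piv = sub.pivot(index="year", columns="reach_id", values="lp50")
    status = sub.pivot(index="year", columns="reach_id", values="status")
    piv.attrs["status"] = status
    return piv


def build_rank_matrix(table: pd.DataFrame, direction: str) -> RankMatrix:
    """Sort a years x reaches table into the percentile-plot layout.

    direction="exposure" (PECmax): within each column the years are sorted
    ascending top-to-bottom (maximum at the bottom); columns are ordered
    by descending column maximum, so the highest value lands bottom-left.

    direction="effect" (LP50): within each column the years are sorted
    descending top-to-bottom (lowest LP50 at the bottom); columns are
    ordered by ascending column minimum, lowest LP50 bottom-left.
    Sentinels rank as larger than any finite margin.

    Accepts either a pivot (index=year, columns=reach_id) or a long PEC
    table.  Ties in the column key break by reach id.
    """
    if direction not in ("exposure", "effect"):
        raise ConfigurationError("direction must be 'exposure' or 'effect'")
    if not isinstance(table.index, pd.MultiIndex) and "pec_max_ug_per_l" in table.columns:
        piv = table.pivot(index="year", columns="reach_id",
                          values="pec_max_ug_per_l")
        status = None
    else:
        piv = table
        status = table.attrs.get("status")

    vals = piv.to_numpy(float)
    reach_ids = list(piv.columns)
    n_years, n_reach = vals.shape

    if direction == "exposure":
        sorted_cols = np.sort(vals, axis=0)  # ascending: max at bottom
        col_key = vals.max(axis=0)
        order = sorted(range(n_reach), key=lambda j: (-col_key[j], reach_ids[j]))
    else:
        sorted_cols = -np.sort(-vals, axis=0)  # descending: min at bottom
        col_key = vals.min(axis=0)
        order = sorted(range(n_reach), key=lambda j: (col_key[j], reach_ids[j]))

    values = sorted_cols[:, order]
    ids = [reach_ids[j] for j in order]

    sentinel = np.zeros_like(values, dtype=np.int8)
    if direction == "effect":
        sentinel[np.isinf(values)] = 1
        if status is not None:
            no_exp_reach = (status == NO_EXPOSURE).all(axis=0)
            for jj, j in enumerate(order):
                if bool(no_exp_reach.iloc[j]):
                    sentinel[:, jj] = 2
    return RankMatrix(values=values, column_reach_ids=ids,
                      sentinel=sentinel, direction=direction)


def fraction_exceeding(
    matrix: RankMatrix, bound: float, at_most_years: float
) -> float:
    """Fraction of reaches beyond ``bound`` in at most the given fraction
    of years (and in at least one year).

    "Beyond" is direction-dependent: value > bound for exposure, finite
    value < bound for effect (smaller LP50 = worse).  ``at_most_years`` is
    a fraction in [0, 1]; 1.0 yields the plain fraction of reaches ever
    beyond the bound.
    """
    if not math.isfinite(bound):
        raise ConfigurationError("bound must be finite")
    vals = matrix.values
    n_years = vals.shape[0]
    if matrix.direction == "exposure":
        hits = (vals > bound).sum(axis=0)
    else:
        hits = (np.isfinite(vals) & (vals < bound)).sum(axis=0)
    qualifying = (hits >= 1) & (hits <= at_most_years * n_years + 1e-9)
    return float(qualifying.sum()) / vals.shape[1]


def _worst_year_value(values: np.ndarray, statuses: np.ndarray,
                      p: float) -> tuple[float, str]:
    """Value at the lower p-th percentile year of one reach using the
    count-based order statistic (ceil), so p=5 with 20 years picks the
    minimum.  Ordering: finite ascending, then ABOVE_CUTOFF, then
    NO_EXPOSURE."""
    rank_class = np.where(statuses == OK, 0,
                          np.where(statuses == ABOVE_CUTOFF, 1, 2))
    order = np.lexsort((values, rank_class))
    n = len(values)
    k = max(1, math.ceil(p / 100.0 * n)) - 1
    i = order[k]
    return float(values[i]), str(statuses[i])


def categorize_lp50(
    lp50_table: pd.DataFrame,
    species: str,
    variant: str,
    year_percentile: float = 5.0,
) -> pd.DataFrame:
    """Worst-year LP50 category per reach (the map layer of the local
    risk view).

    Bins are left-closed: [0,1) -> "<1", [1,10) -> "1-10", [10,100) ->
    "10-100", [100,1e5) -> "100-1e5"; ABOVE_CUTOFF years are
    "effect-free" and never-exposed reaches "no-exposure".
    """
    piv = lp50_pivot(lp50_table, species, variant)
    status = piv.attrs["status"]
    rows = []
    for rid in piv.columns:
        vals = piv[rid].to_numpy(float)
        stats = status[rid].to_numpy(object)
        v, s = _worst_year_value(vals, stats, year_percentile)
        if s == NO_EXPOSURE:
            cat = "no-exposure"
        elif s == ABOVE_CUTOFF:
            cat = "effect-free"
        elif v < LP50_BIN_EDGES[0]:
            cat = "<1"
        elif v < LP50_BIN_EDGES[1]:
            cat = "1-10"
        elif v < LP50_BIN_EDGES[2]:
            cat = "10-100"
        elif v < LP50_BIN_EDGES[3]:
            cat = "100-1e5"
        else:
            cat = "effect-free"
        rows.append((rid, cat, v if s == OK else math.inf))
    return pd.DataFrame(rows, columns=["reach_id", "category", "worst_lp50"])
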