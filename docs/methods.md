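# Methods

This note documents the models implemented in `aquarisk`, the parameters
that matter, the numerical choices, and what the synthetic scenarios do
and do not represent.

## Scenario model

A landscape scenario is a river network (directed tree with a single
outlet), orchard polygons, a wind rose, forcing series (hourly outlet
discharge, daily temperature) and configuration (substance, application,
simulation period). All coordinates are planar metres in a projected CRS;
drift distances and buffer widths are metric, so no geographic
reprojection is ever attempted.

Reaches carry trapezoidal cross sections (bottom width `b` m, bank slope
`s` as horizontal run per unit rise, `s = 0` meaning rectangular),
Manning's `n`, longitudinal slope, contributing drainage area and an
assumed drift-interception water-surface width. Strahler orders follow
the classical rule (headwaters are order 1; the order increments at a
junction only when two or more tributaries share the maximum order) and
are used to assign channel geometry through an order → geometry lookup,
mirroring the common practice of parameterizing many small reaches by
stream order rather than by survey.

Daily temperature is preprocessed to the trailing mean of the three
preceding days before it reaches the fate model; the first three days are
padded with the first complete mean, an artefact wholly absorbed by the
warm-up period.

Orchard-to-reach drift distance is the minimum Euclidean distance from
the orchard polygon to the reach centreline minus half the drift surface
width, floored at zero. A single representative distance is used per
orchard–reach pair because reaches are ~100 m long and deposition is
modelled as the mean areic rate over the reach's water surface.

## Synthetic catchment generator

The generator emulates a mid-size lowland orchard catchment divided into
~100 m reaches:

* **Topology** — a random dendritic tree grown reach by reach; each new
  reach either extends a headwater chain or converts a pass-through reach
  into a junction (upstream degree capped at 2) with probability
  `branch_prob`. The default 0.46 was chosen so that a ~200-reach network
  has roughly 55 % order-1 reaches, the headwater-dominated composition
  typical of dense lowland drainage networks.
* **Lengths** — normal(100, 15) m clipped to [5, 110] m.
* **Drainage area** — a lognormal local increment per reach (mean 9 ha)
  accumulated downstream, giving areas consistent with ~100 m reaches in
  a ~10–20 km² catchment.
* **Discharge** — mean outlet discharge = specific yield (default
  10 L s⁻¹ km⁻²) × area, modulated by a winter-peaked seasonal sinusoid
  (amplitude 0.6) and AR(1) lognormal daily noise (σ = 0.3, ρ = 0.85).
  The resulting April depths (≈0.01–0.2 m) and residence times (minutes,
  longest in order-1 reaches, shortest at the outlet) have the magnitude
  expected of such catchments.
* **Temperature** — seasonal sinusoid (10 ± 8 °C, peak mid-July) plus
  N(0, 1.5) daily noise.
* **Orchards** — a configurable fraction of reaches (default 0.35) is
  flanked by a rectangular orchard (120 m × 80 m) at a uniform random
  edge-to-centreline distance of 3–40 m, on a random side.
* **Wind rose** — eight sectors with a south-westerly dominance.

All draws come from one seeded generator; identical `(n_reaches, seed,
params)` produce byte-identical scenario directories.

What the generator does **not** emulate: realistic planform geometry
(reaches are straight segments and branches may overlap visually),
spatial correlation of orchards with soil/valley position, multi-gauge
hydrology, tile drains, or reach-to-reach heterogeneity of channel
geometry within a Strahler order. Passing tests on synthetic catchments
therefore demonstrates correctness and internal consistency of the
algorithms, not predictive skill for any real catchment.

## Hydrology

The catchment-area-yield approach scales the outlet discharge to each
reach: `Q_r(t) = Q_outlet(t) · A_r / A_outlet`. This preserves downstream
monotonicity of discharge and needs a single gauge; splitting between
multiple gauges is an extension point. Depth is the normal-depth solution
of Manning's equation, `Q = (1/n) A R^{2/3} S^{1/2}` with
`A = d(b + s d)`, `P = b + 2d√(1+s²)`, `R = A/P`, solved by bisection on
[floor, 10 m] to 1e-8 m. Manning discharge is strictly monotone in depth,
so bisection is unconditionally safe (Newton was rejected because of the
derivative corner at `s = 0`). Zero discharge returns the configured
minimum depth floor (default 0.01 m) so reach volume never vanishes.
Velocity is `Q/A`; volume is `A · length`; residence time is
`60 · V / Q` minutes, with `Q = 0` mapped to an infinite-residence
sentinel. Precomputed per-reach series can be ingested from CSV,
bypassing disaggregation entirely.

## Application and drift

One application per orchard per year (date uniform in the configured
window, at noon; default 12.5 g a.i. ha⁻¹, April 20–30). One wind
direction is drawn per application event from the wind rose (bin by
probability, uniform within bin). A reach is downwind when the bearing
from the orchard centroid to its nearest point lies within ±45°
(configurable; inclusive at the boundary) of the downwind direction.

Deposition follows a single power law: at distance `z` metres the areic
deposition is `A·z^B` percent of the applied rate (defaults A = 60.4,
B = −1.22, valid 3–250 m — an illustrative pome-fruit-like
parameterization; regulatory applications must supply the locally
applicable regression). The curve is averaged analytically over the
water-surface band `[z_eff, z_eff + width]`. Mitigation: the buffer acts
as a minimum effective drift distance (`z_eff = max(distance, buffer)`),
and drift-reducing technology multiplies deposition by
`(1 − drift_reduction)` (default 0.75). Deposited mass = areic mean ×
drift surface width × reach length, i.e. the whole reach surface is
treated as exposed for a downwind reach — consistent with modelling the
*mean* areic rate per reach rather than a per-metre discretization.
Deposition is exactly linear in rate and in `(1 − drift_reduction)` and
non-increasing in distance.

## Fate

Each reach is a well-mixed bucket with a water column (dissolved + sorbed
to suspended solids) and a single well-mixed sediment layer (pore water +
sorbed). Within a reach-hour, with discharge `Q`, volume `V` and bed area
`b·L`:

* advection exports water-column mass at rate `Q/V` (sorbed-to-suspended
  mass advects with the water);
* degradation at `ln2/DT50`, Arrhenius-corrected by
  `exp(−E_a/R (1/T − 1/T_ref))` (default E_a 65.4 kJ mol⁻¹, T_ref 20 °C,
  applied to both compartments);
* water–sediment diffusive exchange with flux
  `v_ex · bed_area · (C_dissolved − C_pore)`, where the dissolved
  fraction is `f_d = 1/(1 + K_oc · f_oc,ss · SS)` and the pore-water
  concentration follows from the sediment layer's capacity
  `θ + K_oc · f_oc,sed · ρ_b`;
* optional first-order volatilization of the dissolved fraction
  (default 0; the default substance is non-volatile).

Drift mass and upstream inflow mix instantly over the reach. Reaches are
processed in topological order within each hour, so upstream outflow
reaches the downstream neighbour in the same hour (one-hour output
resolution with minute-scale residence times makes the alternative
next-hour hand-off distort transport).

**Numerics.** Residence times are minutes while the output step is an
hour, so each reach-hour is integrated with operator splitting in
sub-steps no longer than a quarter of `min(V/Q, 1 h)` (capped at 4000).
Within a sub-step every first-order loss from a compartment is applied as
one exact exponential and attributed to its processes in proportion to
their rates; cross-compartment transfers are credited at the sub-step
end. Consequences, all verified by tests: exact mass conservation (the
ledger closes to machine precision), exact linearity in inputs (which is
what justifies the LP50 multiplication-factor approach downstream), and
exactness whenever a compartment has no incoming transfer — in
particular the pure-advection pulse reproduces the continuously-stirred
tank closed form. Hourly water concentration is reported as the
time-weighted mean of total water-column concentration; sediment
concentration as end-of-hour µg per kg dry sediment.

Deviation from multi-layer sediment models: the sediment is one
well-mixed layer (default 5 cm, porosity 0.6, bulk density 0.8 kg/L).
This sacrifices the vertical concentration profile within the bed but
keeps the water-column dynamics — the exposure surface — intact. The
suspended-solids and sediment system parameters are illustrative
defaults and are recorded in every run's configuration echo.

## Effects (reduced GUTS) and LP50

Toxicokinetics: scaled damage `dD/dt = k_d (C − D)`, `D(0) = 0`,
integrated exactly per hour for piecewise-constant exposure
(`D_{t+1} = C_t + (D_t − C_t) e^{−k_d Δt}`). Toxicodynamics:

* **SD** — hazard `h = b·max(D − z, 0) + h_b`; survival
  `S(t) = exp(−∫h)`, with the hazard integral accumulated by the
  trapezoidal rule on the hourly grid;
* **IT** — log-logistic threshold distribution
  `F(x) = 1/(1 + (x/m_w)^{−β})` (computed through the logistic sigmoid
  to avoid overflow); survival `(1 − F(max_{τ≤t} D)) e^{−h_b t}`.

The LP50 of a reach-year is the factor `f` with
`S_f(T_end)/S_0(T_end) = 1/2`, where `S_0` is the unexposed control —
the *relative* reading, which cancels the background hazard analytically;
the absolute reading was rejected because a nonzero `h_b` would bound
feasibility of the 50 % level for long windows. `f` is found by bisection
on log10 f to a relative tolerance of 1e-4; the ratio is monotone in `f`
because damage scales linearly with the profile. All-zero profiles (and
`k_d = 0`) yield the NO_EXPOSURE sentinel (infinite margin); profiles
needing `f > 1e5` yield ABOVE_CUTOFF. Years are independent — damage and
survival restart every January 1st, so multi-year carry-over of damage is
deliberately not represented. Both variants are always computed. The
three shipped species parameter sets are placeholders spanning a
plausible sensitivity range for a pyrethroid-like compound and are
labelled as such.

## Risk end points

PECmax is the annual maximum of hourly averaged water concentration per
reach; values below the 1e-6 µg/L reporting floor are flagged. Overall
percentiles pool all reach-years; both the interpolated (linear between
order statistics) and count-based (inverted CDF) estimators are exposed,
because "k out of n years" statements correspond to the count form while
the interpolated form is the conventional default. LP50 sentinels rank
*after* every finite margin (they are no-concern classes); a pooled
percentile that lands on a sentinel is an error rather than a number.

Rank matrices sort years within each reach (worst at the bottom) and
reaches by their worst year (worst column leftmost), so the worst
reach-year occupies the bottom-left corner; ties in the column key break
by reach id. The exceedance fraction counts reaches beyond a bound in at
least one and at most a given fraction of years. Worst-year category
maps pick each reach's year at the lower 5th percentile using the
count-based order statistic — with 20 assessment years that is exactly
the worst year — and bin the value into {<1, 1–10, 10–100, 100–1e5,
effect-free, no-exposure} with left-closed bins (the labels alone do not
fix the convention; left-closed is the conservative reading since an
exact boundary value falls in the higher-risk-adjacent bin's right
neighbour).

## Orchestration

The pipeline runs scenario → hydrology → drift → fate → effects → risk,
with every stage reading inputs from and writing products to the run
directory only; deleting an intermediate product and re-running from
that stage reproduces identical downstream outputs. The master seed
spawns named child streams (generator, application dates, wind) so that
component-level reproducibility survives changes to the other
components. Multi-decade array products (hydrology, concentrations) are
stored at single precision — ample for exposure analysis — while all
in-memory computation is double precision. A manifest records the
configuration echo, its hash, the seed, derived component seeds, package
version and stage timings.

Problem sizes used by the shipped verification suite and the
reproduction script — 100–200 reaches, 3–26 simulated years — were
chosen as the smallest sizes at which every landscape-scale pattern of
interest (order-dependent residence times, transfer-only exposure of
high-order reaches, year-to-year LP50 spread) is expressed.

## Known limitations

* Spray drift is the only entry route; runoff, erosion and drainage are
  out of scope.
* No longitudinal dispersion within a reach; no backwater or
  hydrodynamic routing — transport is a CSTR cascade driven by the
  area-yield scaling.
* Single-layer sediment; no suspended-solids dynamics; no metabolites.
* GUTS outputs are individual survival only — no population dynamics or
  recovery, and no confidence intervals on LP50.
* The drift curve is a configurable parameterization, not a re-fit of
  experimental deposition data.
* One application per orchard per year; multi-application programmes
  would need an extended application model.
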