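# Methods

This note documents the model, its parameters and numerical choices, what
the synthetic-data generator does and does not emulate, and the package's
known limitations.

## Estimation model

Bycatch in a spatial unit is assumed proportional to the product of turtle
abundance and fishing effort, with a gear-specific constant of
proportionality (catchability).  With observed count `T_b`, modelled
abundance `T_p` and harmonized effort `F` in a unit-year, the rate
`q = T_b/(T_p·F)` is a *minimum* rate: all bycatch in the unit is assumed
observed, and units without observed bycatch are not considered.  Two
opposing biases follow. Assuming complete observation biases `q` low;
conditioning on units that recorded bycatch biases it high (an observed
count is ≥ 1 even where the expected count is below 1).  The test suite
demonstrates both regimes: with expected counts ≥ 50 in observed units the
geometric-mean rate recovers the generating catchability within a few
percent, while at expected counts < 1 it provably overestimates.  The
estimator therefore measures *relative* risk across gears more reliably
than absolute magnitude, and that is how its outputs should be read.

Rates for a species–gear are pooled by geometric mean, which limits the
influence of extreme rates spanning orders of magnitude; the pooling is
justified by first checking for temporal trend in `ln q` against year
(ordinary least squares; `R²`, `p`, `n` are reported).  Uncertainty is
expressed by the geometric means of the rates strictly below and strictly
above the overall geometric mean.  Annual totals multiply the pooled rate
by the summed risk index `R = T_p·F`; the lower/upper rate variants
propagate to bound series.  Percent of population divides the summed
annual bycatch across gears by the modelled coastal population in that
year.

Two identities pin the implementation down and are tested exactly: a rate
computed from a single unit and extrapolated over that unit returns `T_b`;
and scaling all `T_p` (or all `F`) by any `c > 0` leaves every annual total
unchanged, because rates scale as `1/c` while risk scales as `c`.

## Effort harmonization

Conversions use the published constants directly — 128.9 km per trawl-day
in the Gulf of Mexico, 115.6 in the Atlantic, a 0.2083-day (5 h) assumed
longline soak — rather than recomputing them from speeds in knots, so
outputs match the printed figures bit-for-bit; a tested helper
(`knots_to_km_per_day`) documents the derivation.  The Atlantic shrimping
back-fill multiplier is 0.225 (Atlantic effort averaged 77.5 % below Gulf),
and the Atlantic sub-region weights (EFL 0.085, GA 0.189, SC 0.360, NC
0.365; observer-trip alternative 0.418/0.139/0.177/0.266) are applied
without renormalizing their 0.999 sum — the literal published procedure.
A basin-wide final-year total is partitioned by the prior year's relative
distribution.  Area-level effort is divided evenly over the area's member
bins; bin membership is configuration data (a CSV of `area_label, bin_lat,
bin_lon`), not code, because published sources enumerate bin counts for
only a few states and because the synthetic world defines its own
geography.

All conversions are linear and homogeneous (`f(cx) = cf(x)`, `f(0) = 0`)
and rasterization conserves area totals to machine precision; both are
property-tested.

## Recruitment model

Grid cells are half-open 1° squares identified by `(floor(lat),
floor(lon))`, so boundary points have unambiguous owners.  Advection
integrates in degrees under an equirectangular projection with a fixed
reference latitude (the grid's mid-latitude); over the ~10° domains used
here the metric distortion is small, and a constant projection makes RK4
exactly linear in a uniform flow — the basis of a machine-precision test.
Velocities are sampled bilinearly in space and linearly in time, a standard
tracer-advection choice.  The kernel is fourth-order: on a solid-body
rotation the orbit radius drifts < 1e-6 relative over a full period at
half-hour steps, and halving the step shrinks the end-of-orbit error ~16×.

Particles that step off the grid are frozen at their last in-grid position
and flagged, never dropped, so the particle budget is conserved; in the
synthetic world the western grid edge plays the coastline, and frozen
particles in coastal bins count as recruits (there is no separate beaching
model).  Release schedules default to the full design — 350 particles/day
over a 60-day emergence window, 21,000 per region-year — with optional
seeded positional jitter standing in for release "offshore of" a nesting
site.

Ages are sampled at `a · 365.25` days, snapped to the nearest stored
half-hour step (the day convention is not otherwise determined).  Survival
uses a daily rate `s_d = 0.817^(1/365)`, applied continuously in age as
`s_d^(365a) = 0.817^a`, which reproduces the annual median exactly at
integer ages.  A turtle of age `a` counted in calendar year `y` is assigned
to hatch cohort `y − ⌈a⌉` (age 0.5 in 2000 reads the 1999 cohort); the
offset is configurable since other conventions are defensible.  A cohort
year missing from the hatchling table raises an error rather than silently
contributing zero.  Abundance per bin-year sums
`H(region, cohort) · p(bin, region, age) · 0.817^age` over regions and ages
up to the species cap (Kemp's ridley 2.5 yr, green 3.5 yr).

## Synthetic world

The generator emulates the *shapes and statistical structure* of the real
inputs: per-gear raw effort tables in native units with linear annual
trends and multiplicative lognormal noise (effort stays positive);
hatchling production with growth and lognormal noise; gridded velocity
fields; and bycatch observed through `T_b ~ Poisson(q_true·T_p·F)`, at bin
level for commercial gears and at state level for recreational records
(mirroring how such records are aggregated).  One root seed fans out to
named child streams via `SeedSequence(entropy=seed, spawn_key=(k,))`, so a
fixed seed gives bit-identical outputs and components can be regenerated
independently.

Flows are analytic (uniform, solid rotation, double gyre) precisely because
they admit closed-form reference trajectories; gridded NetCDF fields from
an ocean model can be substituted through the same reader.  The generator
does **not** emulate survey design, logbook reporting behaviour, observer
coverage fractions, swimming behaviour, or mesoscale ocean variability —
so passing tests demonstrate the correctness of the arithmetic and the
estimator's statistical behaviour under its own assumptions, not the
fidelity of any real-world prediction.

The demo configuration used by the examples, tests and acceptance script is
a desk-scale reduction chosen to keep a full pipeline run in seconds: a
10°×10° grid whose western bin column is the coast, three nesting regions,
two species, three gears (shrimp trawl, gillnet at statistical-zone level,
recreational at state level), ten years, 8 particles/day over 10-day
windows, and age classes {0.5, 1.5} yr.  Its effort and production scales
were chosen once so that the expected count in every observed unit exceeds
50, the regime in which geometric-mean recovery of a constant catchability
is meaningful; recovered rates then sit within a few percent of truth,
Poisson sampling being the only noise source.  The full release design
remains the default of `ReleaseSchedule` itself.

## Numerical choices

* Geometric means are computed in log space; brackets use strict
  inequalities, with values within 1e-12 relative of the GM treated as
  ties belonging to neither bracket (a singleton's GM round-trips through
  `exp(mean(log))` with float error; without the tolerance it would
  spuriously acquire a bracket).
* Years with zero extrapolated bycatch are excluded from the annual
  geometric mean rather than mapped to zero (a zero would annihilate it);
  gears with no observed bycatch are dropped from the summary entirely.
* Records with `T_b > 0` but `T_p·F = 0` are returned as excluded records
  and logged, never silently dropped.
* Trend tests are two-sided Pearson correlations with t-distribution
  p-values and no multiple-testing correction; constant series report NaN.
* Rate-trend screening runs on `ln q`, consistent with geometric-mean
  pooling; the scale is recorded in the output.
* The supplement-workbook reader treats four-digit column headers as bin
  centres (first pair °N, second pair °W); since the risk index is exactly
  the rate denominator, counts joined to risk cells reproduce the whole
  chain deterministically from one file.
* CSVs are written with a fixed 12-significant-digit float format so equal
  seeds give byte-identical files.

## Limitations

Only juveniles recently recruited from the oceanic stage are modelled; no
swimming behaviour, habitat selection, or adult distributions.  The
observation model assumes complete observation within units and equal
catchability across habitats within a gear.  Absolute bycatch magnitudes
are therefore indicative; relative risk across gears is the supported
conclusion.  The equirectangular projection and analytic flows are adequate
for the demo domain but are stand-ins for a proper ocean-model velocity
archive in any real application.
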