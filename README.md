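# bycatchrisk

Estimating sea-turtle bycatch risk in coastal fisheries from the spatial
overlap between fishing effort and drift-modelled juvenile recruitment.

## The problem

Bycatch — the unintentional capture of non-target species — is a leading
threat to juvenile Kemp's ridley (*Lepidochelys kempii*) and green
(*Chelonia mydas*) sea turtles as they recruit from oceanic to nearshore
habitats.  Observed bycatch alone is a poor risk gauge because it conflates
three things: how much fishing happens, how many turtles are present, and
how catchy a gear is.  This package separates them.  It is written for
quantitative ecologists and fisheries analysts who want a tested, reusable
implementation of the approach, with a synthetic-data generator that makes
every stage verifiable without any external download.

## The model

For each spatial unit (1°×1° bin, or a state/area for records only known at
that level) with observed bycatch, the **minimum bycatch rate** of a gear is

```
q = T_b / (T_p · F)
```

where `T_b` is the observed bycatch count, `T_p` the modelled juvenile
abundance and `F` the harmonized fishing effort in that unit-year.  Units
without observed bycatch contribute no rate.  Per species–gear the rates are
pooled by **geometric mean**, bracketed by the geometric means of the rates
below and above it (rendered `--` when a bracket set is empty).  Annual
totals are extrapolated over the **risk index** `R = T_p · F`:

```
B_y = GM(q) · Σ_bins R(bin, y),      P_y = 100 · Σ_gears B_y / Σ_bins T_p(bin, y)
```

The ingredients:

* **Effort harmonization** — gear-native units (days trawled; sets × length
  × soak; lines × hours; angler trips) are converted to gear-standard
  exposure units (km trawled at 128.9/115.6 km per day for Gulf/Atlantic,
  km·days, line·days, angler·days), with the documented back-extrapolation
  (Atlantic shrimping = 0.225 × Gulf before 2007), fixed sub-region weights,
  prior-year partitioning of basin-wide totals, and even spreading of
  area-level effort over each area's coastal bins.
* **Recruitment** — each nesting region's annual cohort is released as
  passive particles (350/day over a 60-day emergence window), advected with
  fourth-order Runge–Kutta at half-hour steps through gridded surface
  velocities (bilinear in space, linear in time).  The fraction of particles
  in coastal bins at ages 0.5–3.5 yr, scaled by hatchling production and
  oceanic survival (81.7 %/yr), gives `T_p`.  Species differ in drift span
  (Kemp's ridley ≤ 2.5 yr, green ≤ 3.5 yr).
* **Synthetic world** — analytic flows (uniform, solid rotation, double
  gyre), seeded effort trends, and a Poisson observation model
  `T_b ~ Poisson(q_true · T_p · F)` with known `q_true`, so the estimator
  can be validated by parameter recovery.

## Worked example

`examples/04_bycatch_estimation.py` runs the whole chain on the seeded demo
world (2 species × 3 gears × 10 years) and prints, among other tables:

```
recovery of the generating catchability (1.0 = perfect):
     species         gear  n  recovered/true
       green      gillnet 60        1.001160
       green recreational 40        0.995035
       green shrimp_trawl 60        0.985099
kemps_ridley      gillnet 60        0.987693
kemps_ridley recreational 40        1.002452
kemps_ridley shrimp_trawl 60        1.003345

effort trends (Pearson r of total effort vs year):
        gear         r        p  n
     gillnet  0.808468 0.004639 10
recreational  0.843215 0.002178 10
shrimp_trawl -0.888928 0.000581 10
```

The recovered/true column compares the estimated geometric-mean rate with
the catchability that generated the observations — all gears land within
1.5 % here, Poisson noise being the only error source.  The trend table
recovers the built-in declining trawl trend and rising gillnet/recreational
trends.  The other examples cover effort harmonization, the advection
kernel against closed-form orbits, recruitment/abundance, and the
observer-series comparison assembly.

## Command line

A thin CLI orchestrates the stages with a YAML config and one root seed:

```
bycatchrisk simulate  --outdir out --seed 1    # synthetic bundle + manifest
bycatchrisk harmonize --outdir out             # raw effort -> per-bin units
bycatchrisk recruit   --outdir out             # drift -> abundance grid
bycatchrisk estimate  --outdir out             # rates, summaries, totals
bycatchrisk report    --outdir out             # print the summary tables
```

Exit codes: 0 ok, 2 configuration error, 3 data error.  Rerunning with the
same seed produces byte-identical outputs.

Real supplementary-style workbooks (sheets `Bycatch`, `Shrimp_Risk`, …,
with bin centres encoded as lat/lon digit-pair column headers) can be
ingested with `bycatchrisk.supplement.estimate_from_supplement`, which
reproduces the rate → geometric-mean → extrapolation chain deterministically
from such a file.

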