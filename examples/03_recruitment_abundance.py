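"""From particle drift to juvenile abundance per coastal 1-degree bin.

A nesting region's cohort is released offshore, drifts with the current,
and the fraction found in coastal bins at each age snapshot is scaled by
hatchling production and oceanic survival (81.7%/yr) into abundance T_p.
"""

import pandas as pd

from bycatchrisk import (
    classify_coastal_recruits,
    daily_survival,
    demo_world,
    drift_region,
)
from bycatchrisk import abundance, age_composition, aggregate_abundance
from bycatchrisk.synthetic import component_rng, gen_velocity_field

world = demo_world(seed=0)
velocity = gen_velocity_field(world)
sched = world.schedules()[0]  # the "south" nesting region
print(f"region {sched.region!r}: {sched.particles_per_day}/day x "
      f"{sched.window_days} d = {sched.particles_per_day * sched.window_days} particles")

rng = component_rng(world.seed, "release")
traj = drift_region(velocity, sched, world.age_classes, rng=rng)
frac = classify_coastal_recruits(
    traj, world.grid, set(world.coastal_bins), world.age_classes, sched.region
)
print("\ncoastal recruitment fractions (share of released particles per bin):")
print(frac.to_string(index=False))

print(f"\ndaily survival from 81.7%/yr: {daily_survival():.6f}")

hatchlings = pd.DataFrame(
    {"region": sched.region, "year": range(1997, 2001), "hatchlings": 50_000.0}
)
comp = abundance(hatchlings, frac, "kemps_ridley", years=[2000])
print("\nabundance components (hatchlings x fraction x survival):")
print(comp.to_string(index=False))
print("\naggregated T_p per bin:")
print(aggregate_abundance(comp).to_string(index=False))
print("\nage composition of coastal recruits (% per age class):")
print(age_composition(comp).to_string(index=False))
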