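"""Convert raw fishing-effort records into gear-standard exposure units.

Each gear reports effort in its own native units; harmonization puts them
on scales proportional to how much gear is in the water and for how long.
"""

from bycatchrisk import effort

print("1 day of Gulf trawling     ->", effort.convert_trawl_effort(1.0, "gulf"), "km")
print("1 day of Atlantic trawling ->", effort.convert_trawl_effort(1.0, "atlantic"), "km")
print("10 km longline set x 1 set ->", effort.longline_effort(10.0, 1), "km*days")
print("24 angler trips in Texas   ->", effort.recreational_effort(24, "TX"), "angler*days")

# Early Atlantic shrimping effort is reconstructed from the Gulf series
# (Atlantic effort averaged 77.5% less, hence the 0.225 multiplier) ...
atlantic = effort.extend_atlantic_shrimp(
    gulf_series={1996: 100_000.0, 1997: 90_000.0},
    atlantic_series={2007: 20_000.0},
    backfill_years=[1996, 1997, 2007],
)
print("\nAtlantic shrimp series (back-filled 1996-97, observed 2007):")
print(atlantic.to_string())

# ... and split across sub-regions with fixed trip-share weights.
parts = effort.partition_atlantic_shrimp(atlantic[1996])
print("\n1996 Atlantic effort by sub-region (weights sum to 0.999, unrenormalized):")
for region, value in parts.items():
    print(f"  {region}: {value:.1f}")

# Area-level effort is spread evenly over the area's 1-degree bins.
import pandas as pd

area = pd.DataFrame(
    [{"gear": "recreational", "year": 2000, "area_label": "TX",
      "effort": 100.0, "unit": "angler*days"}]
)
bins = effort.rasterize_effort(area, {"TX": [(24, -90), (25, -90), (26, -90), (27, -90)]})
print("\nTexas effort split over its 4 coastal bins (totals conserved):")
print(bins.to_string(index=False))
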