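"""Synthetic world with known ground truth for end-to-end verification.

Every pipeline input — velocity fields, hatchling production, raw effort
tables, observed bycatch — can be generated here with known generating
parameters (true catchability per gear, known flow, known production), so
each downstream stage is testable by recovery of what went in.

The default demo geography is a 10x10-degree ocean whose western column of
bins is the "coast", carved into state-like areas that reuse real state
codes (TX: 4 bins, LA: 3, SC: 2, MS: 1) so the recreational trip-duration
table applies; trawl areas and gillnet zones tile the same coastline.
Surface flow is a gentle westward drift, so particles released offshore
beach on the coastal column within their first half-year.

Randomness: one root seed is fanned out to named per-component child
streams via ``numpy.random.SeedSequence(entropy=seed, spawn_key=(k,))``
with a fixed component -> k map, so components can be regenerated
independently and a fixed seed gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from . import flows
from .errors import AlignmentError, ConfigError
from .grid import BinId, Grid, Membership
from .recruitment import SPECIES_AGE_CAP, ReleaseSchedule

#: component -> spawn key for seed fan-out
_SEED_COMPONENTS = {"hatchlings": 0, "effort": 1, "release": 2, "bycatch": 3}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Child generator for a named component of the synthetic world."""
    if component not in _SEED_COMPONENTS:
        raise ConfigError(f"unknown seed component {component!r}")
    ss = np.random.SeedSequence(
        entropy=int(seed), spawn_key=(_SEED_COMPONENTS[component],)
    )
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class NestingRegion:
    """One nesting region: release site plus a hatchling-production model.

    Production follows H(y) = h0 * (1 + growth*(y - year0)) with seeded
    multiplicative lognormal noise (production stays positive).
    """

    name: str
    release_lat: float
    release_lon: float
    h0: float = 100_000.0
    growth: float = 0.04
    noise_sigma: float = 0.10


@dataclass(frozen=True)
class GearSpec:
    """One fishery: true catchability, raw-unit model, and spatial weights.

    ``q_true`` maps species -> catchability in the gear's standard units.
    ``base`` is the trend-carrying raw quantity (days trawled, sets, trips,
    lines) per area at ``year0``; effort follows base * (1 + slope*dy) with
    multiplicative lognormal noise.  ``params`` holds the remaining raw
    columns (set length, soak, hours).  ``bycatch_level`` is "bin" for
    gears whose observations are bin-resolved and "area" for records only
    known at state/area level (recreational).
    """

    name: str
    q_true: dict[str, float]
    areas: tuple[str, ...]
    base: float
    slope: float = 0.0
    noise_sigma: float = 0.0
    area_weights: dict[str, float] | None = None
    params: dict[str, float] = field(default_factory=dict)
    basin: str = "gulf"
    bycatch_level: str = "bin"

    def __post_init__(self) -> None:
        for sp, q in self.q_true.items():
            if q < 0:
                raise ConfigError(f"q_true must be >= 0 ({self.name}/{sp})")
        if self.bycatch_level not in ("bin", "area"):
            raise ConfigError("bycatch_level must be 'bin' or 'area'")


@dataclass(frozen=True)
class SyntheticWorld:
    """Complete specification of a synthetic study system."""

    grid: Grid
    coastal_bins: frozenset[BinId]
    membership: Membership
    regions: tuple[NestingRegion, ...]
    gears: tuple[GearSpec, ...]
    flow: dict
    years: tuple[int, ...]
    species: tuple[str, ...]
    age_classes: tuple[float, ...]
    particles_per_day: int = 350
    window_days: int = 60
    release_jitter_deg: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.years:
            raise ConfigError("world needs at least one year")
        for r in self.regions:
            if not self.grid.contains(r.release_lat, r.release_lon):
                raise ConfigError(f"release point of {r.name!r} outside grid")
        for sp in self.species:
            if sp not in SPECIES_AGE_CAP:
                raise ConfigError(f"unknown species {sp!r}")

    @property
    def year0(self) -> int:
        return min(self.years)

    def schedules(self) -> list[ReleaseSchedule]:
        return [
            ReleaseSchedule(
                region=r.name,
                release_lat=r.release_lat,
                release_lon=r.release_lon,
                particles_per_day=self.particles_per_day,
                window_days=self.window_days,
                jitter_deg=self.release_jitter_deg,
            )
            for r in self.regions
        ]

    def q_true_table(self) -> pd.DataFrame:
        rows = [
            {"gear": g.name, "species": sp, "q_true": q}
            for g in self.gears
            for sp, q in g.q_true.items()
        ]
        return pd.DataFrame(rows)


def demo_world(
    seed: int = 0,
    years: tuple[int, ...] = tuple(range(2000, 2010)),
    particles_per_day: int = 8,
    window_days: int = 10,
    age_classes: tuple[float, ...] = (0.5, 1.5),
) -> SyntheticWorld:
    """Small, fully specified demo system: 2 species x 3 gears x 10 years.

    Particle counts and drift ages default to a desk-scale reduction of the
    full release design (the ReleaseSchedule defaults of 350/day over 60
    days remain available by passing them explicitly).
    """
    grid = Grid(lat0=24, lon0=-90, nlat=10, nlon=10)
    coast_lon = -90
    coastal = frozenset((lat, coast_lon) for lat in range(24, 34))
    membership: Membership = {
        # recreational "states" (real codes so the trip-hours table applies)
        "TX": [(lat, coast_lon) for lat in range(24, 28)],
        "LA": [(lat, coast_lon) for lat in range(28, 31)],
        "SC": [(lat, coast_lon) for lat in range(31, 33)],
        "MS": [(33, coast_lon)],
        # shrimp-trawl statistical areas
        "AREA_1": [(lat, coast_lon) for lat in range(24, 27)],
        "AREA_2": [(lat, coast_lon) for lat in range(27, 30)],
        "AREA_3": [(lat, coast_lon) for lat in range(30, 32)],
        "AREA_4": [(lat, coast_lon) for lat in range(32, 34)],
        # gillnet statistical zones
        "Z1": [(24, coast_lon), (25, coast_lon)],
        "Z2": [(26, coast_lon), (27, coast_lon)],
        "Z3": [(28, coast_lon), (29, coast_lon)],
        "Z4": [(30, coast_lon), (31, coast_lon)],
        "Z5": [(32, coast_lon), (33, coast_lon)],
    }
    regions = (
        NestingRegion("south", 25.5, -82.5, h0=100_000.0),
        NestingRegion("mid", 29.5, -82.5, h0=120_000.0),
        NestingRegion("north", 32.5, -82.5, h0=90_000.0),
    )
    gears = (
        GearSpec(
            name="shrimp_trawl",
            q_true={"kemps_ridley": 3e-7, "green": 1.5e-7},
            areas=("AREA_1", "AREA_2", "AREA_3", "AREA_4"),
            base=600.0,  # days trawled per area-year
            slope=-0.03,
            noise_sigma=0.10,
            basin="gulf",
        ),
        GearSpec(
            name="gillnet",
            q_true={"kemps_ridley": 2e-4, "green": 1e-4},
            areas=("Z1", "Z2", "Z3", "Z4", "Z5"),
            base=200.0,  # sets per zone-year
            slope=0.02,
            noise_sigma=0.10,
            params={"mean_set_length_km": 1.5, "soak_days": 0.3},
        ),
        GearSpec(
            name="recreational",
            q_true={"kemps_ridley": 4e-7, "green": 2e-7},
            areas=("TX", "LA", "SC", "MS"),
            base=150_000.0,  # angler trips per state-year
            slope=0.025,
            noise_sigma=0.10,
            bycatch_level="area",
        ),
    )
    return SyntheticWorld(
        grid=grid,
        coastal_bins=coastal,
        membership=membership,
        regions=regions,
        gears=gears,
        flow={"name": "uniform", "u": -0.12, "v": 0.015},
        years=tuple(int(y) for y in years),
        species=("kemps_ridley", "green"),
        age_classes=tuple(age_classes),
        particles_per_day=particles_per_day,
        window_days=window_days,
        release_jitter_deg=0.4,
        seed=int(seed),
    )


def gen_velocity_field(world: SyntheticWorld) -> xr.Dataset:
    """The world's flow sampled on the grid (single snapshot: stationary)."""
    spec = dict(world.flow)
    name = spec.pop("name")
    return flows.gen_velocity_field(name, world.grid, times=[0.0], **spec)


def gen_hatchlings(world: SyntheticWorld) -> pd.DataFrame:
    """Hatchling production H(region, year) incl. pre-study cohort years.

    Cohorts up to ceil(max age) years before the first study year are
    generated so every age class in the first year has a cohort.
    """
    rng = component_rng(world.seed, "hatchlings")
    lookback = int(np.ceil(max(world.age_classes)))
    years = range(world.year0 - lookback, max(world.years) + 1)
    rows = []
    for r in world.regions:
        for y in years:
            trend = r.h0 * max(1.0 + r.growth * (y - world.year0), 0.05)
            noise = (
                float(np.exp(rng.normal(0.0, r.noise_sigma)))
                if r.noise_sigma > 0
                else 1.0
            )
            rows.append({"region": r.name, "year": int(y), "hatchlings": trend * noise})
    return pd.DataFrame(rows)


def _raw_effort_row(gear: GearSpec, area: str, year: int, quantity: float) -> dict:
    row = {"year": year, "area_label": area}
    if gear.name == "shrimp_trawl":
        row.update(days_trawled=quantity, basin=gear.basin)
    elif gear.name in ("gillnet", "bottom_longline"):
        row.update(
            mean_set_length_km=gear.params.get("mean_set_length_km", 1.0),
            n_sets=quantity,
        )
        if gear.name == "gillnet":
            row.update(soak_days=gear.params.get("soak_days", 0.25))
    elif gear.name == "hook_and_line":
        row.update(n_lines=quantity, hours_fished=gear.params.get("hours_fished", 6.0))
    elif gear.name == "recreational":
        row.update(angler_trips=quantity)
    else:
        raise ConfigError(f"no raw-unit model for gear {gear.name!r}")
    return row


def gen_effort(world: SyntheticWorld) -> dict[str, pd.DataFrame]:
    """Raw effort tables per gear, in each gear's native units.

    The trend-carrying quantity follows a linear annual trend with seeded
    multiplicative lognormal noise (effort stays positive); spatial
    allocation follows the gear's area weights (uniform by default).
    """
    rng = component_rng(world.seed, "effort")
    out: dict[str, pd.DataFrame] = {}
    for gear in world.gears:
        if not world.years:
            raise ConfigError("years must be non-empty")
        weights = gear.area_weights or {a: 1.0 for a in gear.areas}
        rows = []
        for year in world.years:
            trend = max(1.0 + gear.slope * (year - world.year0), 0.05)
            for area in gear.areas:
                noise = (
                    float(np.exp(rng.normal(0.0, gear.noise_sigma)))
                    if gear.noise_sigma > 0
                    else 1.0
                )
                qty = gear.base * weights[area] * trend * noise
                rows.append(_raw_effort_row(gear, area, int(year), qty))
        out[gear.name] = pd.DataFrame(rows)
    return out


def gen_bycatch(
    world: SyntheticWorld,
    abundance: pd.DataFrame,
    effort: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observed-bycatch records: counts ~ Poisson(q_true * T_p * F).

    ``abundance`` is the aggregated (species, year, bin_lat, bin_lon, t_p)
    table and ``effort`` the harmonized per-bin table.  Gears with
    ``bycatch_level == "area"`` are observed at area level: the Poisson mean
    uses area-summed T_p and F, and the record carries the area label
    instead of a bin.  Zero-mean cells may still emit zero counts; the
    estimator excludes them.
    """
    if rng is None:
        rng = component_rng(world.seed, "bycatch")
    rows = []
    for gear in world.gears:
        eff = effort[effort["gear"] == gear.name]
        if eff.empty:
            raise AlignmentError(f"no harmonized effort for gear {gear.name!r}")
        for sp, q in gear.q_true.items():
            ab = abundance[abundance["species"] == sp]
            if gear.bycatch_level == "bin":
                merged = ab.merge(eff, on=["year", "bin_lat", "bin_lon"], how="inner")
                if merged.empty:
                    raise AlignmentError(
                        f"abundance and effort share no bin-years ({gear.name}/{sp})"
                    )
                lam = q * merged["t_p"].to_numpy() * merged["effort"].to_numpy()
                counts = rng.poisson(lam)
                for rec, c in zip(merged.itertuples(index=False), counts):
                    rows.append(
                        {
                            "species": sp,
                            "gear": gear.name,
                            "year": int(rec.year),
                            "bin_lat": int(rec.bin_lat),
                            "bin_lon": int(rec.bin_lon),
                            "area_label": "",
                            "count": int(c),
                        }
                    )
            else:
                for area in gear.areas:
                    bins = world.membership[area]
                    for year in world.years:
                        t_pa = ab[
                            (ab["year"] == year)
                            & ab.apply(
                                lambda r: (r["bin_lat"], r["bin_lon"]) in bins, axis=1
                            )
                        ]["t_p"].sum() if not ab.empty else 0.0
                        f_a = eff[
                            (eff["year"] == year)
                            & eff.apply(
                                lambda r: (r["bin_lat"], r["bin_lon"]) in bins, axis=1
                            )
                        ]["effort"].sum()
                        lam = q * t_pa * f_a
                        rows.append(
                            {
                                "species": sp,
                                "gear": gear.name,
                                "year": int(year),
                                "bin_lat": np.nan,
                                "bin_lon": np.nan,
                                "area_label": area,
                                "count": int(rng.poisson(lam)),
                            }
                        )
    return pd.DataFrame(
        rows,
        columns=["species", "gear", "year", "bin_lat", "bin_lon", "area_label", "count"],
    )
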