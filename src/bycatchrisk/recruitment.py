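"""Juvenile coastal recruitment: drift, age snapshots, survival, abundance.

The model treats each nesting region's annual cohort as a cloud of passive
particles released daily over a 60-day emergence window (350 per day by
default, i.e. 21,000 per region-year).  Particles drift with surface
currents; at age snapshots (0.5, 1.5, 2.5, 3.5 years) the fraction located
in coastal 1-degree bins gives the recruitment field p(bin, region, age).
Predicted abundance in a bin then scales that fraction by the cohort's
hatchling production and by oceanic survival:

    T_p(bin, y) = sum over regions, ages a:
        H(region, y - ceil(a)) * p(bin, region, a) * s_d ** (365 * a)

with s_d the daily survival derived from the 81.7% annual oceanic rate.
Species differ in how long they drift: Kemp's ridley up to 2.5 years, green
turtles up to 3.5 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .advection import TrajectorySet, advect_particles
from .errors import ConfigError, MissingDataError
from .grid import BinId, Grid

#: median annual oceanic-stage survival
ANNUAL_SURVIVAL = 0.817

#: days in the survival year (annual -> daily conversion)
SURVIVAL_YEAR_DAYS = 365

#: days per year of age when locating age snapshots along a trajectory
AGE_YEAR_DAYS = 365.25

#: maximum drift age (years) per species
SPECIES_AGE_CAP = {"kemps_ridley": 2.5, "green": 3.5}

#: canonical age classes (years)
AGE_CLASSES = (0.5, 1.5, 2.5, 3.5)


@dataclass(frozen=True)
class ReleaseSchedule:
    """Daily particle releases off one nesting region for one cohort.

    Defaults follow the study design: 350 particles/day over a 60-day peak
    emergence window, i.e. 21,000 particles per region-year.
    """

    region: str
    release_lat: float
    release_lon: float
    particles_per_day: int = 350
    window_days: int = 60
    start_day: float = 0.0
    jitter_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.particles_per_day < 1 or self.window_days < 1:
            raise ConfigError("release schedule needs >=1 particle/day and >=1 day")


def count_particles_per_region_year(schedule: ReleaseSchedule) -> int:
    """Total particles a schedule releases in one cohort year."""
    return schedule.particles_per_day * schedule.window_days


def build_releases(
    schedule: ReleaseSchedule, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand a schedule into per-particle (lon, lat, release_day) arrays.

    With ``jitter_deg > 0`` release positions are uniformly scattered within
    a square of that half-width around the nominal point (seeded), standing
    in for release 'offshore of the primary nesting sites'.
    """
    n = count_particles_per_region_year(schedule)
    days = schedule.start_day + np.repeat(
        np.arange(schedule.window_days, dtype=float), schedule.particles_per_day
    )
    lon = np.full(n, schedule.release_lon)
    lat = np.full(n, schedule.release_lat)
    if schedule.jitter_deg > 0:
        if rng is None:
            raise ConfigError("jittered releases need a random generator")
        lon = lon + rng.uniform(-schedule.jitter_deg, schedule.jitter_deg, n)
        lat = lat + rng.uniform(-schedule.jitter_deg, schedule.jitter_deg, n)
    return lon, lat, days


def drift_region(
    velocity: xr.Dataset,
    schedule: ReleaseSchedule,
    ages_years,
    step_hours: float = 0.5,
    rng: np.random.Generator | None = None,
) -> TrajectorySet:
    """Advect one region's cohort and record positions at the age snapshots."""
    lon, lat, days = build_releases(schedule, rng)
    ages_days = np.asarray(ages_years, dtype=float) * AGE_YEAR_DAYS
    return advect_particles(
        velocity,
        lon,
        lat,
        days,
        duration_days=float(ages_days.max()),
        ages_days=ages_days,
        step_hours=step_hours,
    )


def classify_coastal_recruits(
    trajectories: TrajectorySet,
    grid: Grid,
    coastal_bins: set[BinId],
    ages_years,
    region: str,
) -> pd.DataFrame:
    """Fraction of a region's particles in each coastal bin at each age.

    Positions at the stored step nearest age ``a * 365.25`` days are floored
    into 1-degree bins; only bins flagged coastal count as recruitment.  The
    denominator is all particles released from the region-cohort, so
    fractions over coastal bins sum to <= 1.  Requesting an age beyond what
    the trajectories stored is a contract error.
    """
    ages_years = np.asarray(ages_years, dtype=float)
    stored = trajectories.ages_days / AGE_YEAR_DAYS
    rows = []
    n = trajectories.n_particles
    for a in ages_years:
        match = np.flatnonzero(np.isclose(stored, a, atol=1e-9))
        if match.size == 0:
            raise ConfigError(
                f"age {a} yr not stored in trajectories (stored: {stored.tolist()})"
            )
        k = match[0]
        lons = trajectories.lon_at_age[k]
        lats = trajectories.lat_at_age[k]
        ok = np.isfinite(lons) & np.isfinite(lats)
        blat = np.floor(lats[ok]).astype(int)
        blon = np.floor(lons[ok]).astype(int)
        counts: dict[BinId, int] = {}
        for bl, bn in zip(blat, blon):
            b = (int(bl), int(bn))
            if b in coastal_bins:
                counts[b] = counts.get(b, 0) + 1
        for (bl, bn), c in sorted(counts.items()):
            rows.append(
                {
                    "region": region,
                    "age": float(a),
                    "bin_lat": bl,
                    "bin_lon": bn,
                    "fraction": c / n,
                }
            )
    return pd.DataFrame(
        rows, columns=["region", "age", "bin_lat", "bin_lon", "fraction"]
    )


def daily_survival(annual: float = ANNUAL_SURVIVAL) -> float:
    """Per-day survival whose 365th power reproduces the annual rate."""
    if not 0 < annual <= 1:
        raise ConfigError("annual survival must be in (0, 1]")
    return annual ** (1.0 / SURVIVAL_YEAR_DAYS)


def survival_to_age(age_years: float, annual: float = ANNUAL_SURVIVAL) -> float:
    """Cumulative survival to a given age: s_d^(365*a) = annual^a."""
    return daily_survival(annual) ** (SURVIVAL_YEAR_DAYS * age_years)


def abundance(
    hatchlings: pd.DataFrame,
    fractions: pd.DataFrame,
    species: str,
    years,
    annual_survival: float = ANNUAL_SURVIVAL,
    cohort_offset=None,
) -> pd.DataFrame:
    """Predicted juvenile abundance per bin-year with age components retained.

    ``hatchlings``: (region, year, hatchlings) — cohort production H.
    ``fractions``: (region, age, bin_lat, bin_lon, fraction) — recruitment
    field p, optionally with a ``cohort_year`` column when the flow (and so
    the dispersal) varies between cohorts; without one the same field is
    used for every cohort (stationary flow).

    A turtle of age ``a`` observed in calendar year ``y`` is assigned to the
    hatch cohort ``y - cohort_offset(a)`` (default ``ceil(a)``).  A needed
    cohort year absent from ``hatchlings`` raises — never a silent zero.

    Returns (species, year, region, age, bin_lat, bin_lon, abundance).
    """
    if species not in SPECIES_AGE_CAP:
        raise ConfigError(f"unknown species {species!r}")
    if cohort_offset is None:
        cohort_offset = lambda a: math.ceil(a)  # noqa: E731
    cap = SPECIES_AGE_CAP[species]
    ages = sorted(set(fractions["age"].astype(float))) if len(fractions) else []
    ages = [a for a in ages if a <= cap + 1e-9]
    if not ages:
        raise ConfigError("no usable age classes in recruitment fractions")
    h = hatchlings.set_index(["region", "year"])["hatchlings"]
    per_cohort = "cohort_year" in fractions.columns
    rows = []
    for y in years:
        y = int(y)
        for a in ages:
            cohort = y - int(cohort_offset(a))
            surv = survival_to_age(a, annual_survival)
            sub = fractions[np.isclose(fractions["age"].astype(float), a)]
            if per_cohort:
                sub = sub[sub["cohort_year"] == cohort]
            for rec in sub.itertuples(index=False):
                key = (rec.region, cohort)
                if key not in h.index:
                    raise MissingDataError(
                        f"hatchling production missing for region {rec.region!r}, "
                        f"cohort year {cohort} (needed for age {a} in {y})"
                    )
                rows.append(
                    {
                        "species": species,
                        "year": y,
                        "region": rec.region,
                        "age": float(a),
                        "bin_lat": int(rec.bin_lat),
                        "bin_lon": int(rec.bin_lon),
                        "abundance": float(h.loc[key]) * float(rec.fraction) * surv,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["species", "year", "region", "age", "bin_lat", "bin_lon", "abundance"],
    )


def aggregate_abundance(components: pd.DataFrame) -> pd.DataFrame:
    """Sum age/region components into T_p per (species, year, bin)."""
    return (
        components.groupby(["species", "year", "bin_lat", "bin_lon"], as_index=False)[
            "abundance"
        ]
        .sum()
        .rename(columns={"abundance": "t_p"})
    )


def age_composition(components: pd.DataFrame) -> pd.DataFrame:
    """Per species-year percentage of coastal abundance in each age class.

    Rows (species, year) sum to 100 across age-class columns.
    """
    by_age = components.groupby(["species", "year", "age"], as_index=False)[
        "abundance"
    ].sum()
    total = by_age.groupby(["species", "year"])["abundance"].transform("sum")
    by_age["percent"] = 100.0 * by_age["abundance"] / total
    return by_age.pivot_table(
        index=["species", "year"], columns="age", values="percent", fill_value=0.0
    ).reset_index()
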