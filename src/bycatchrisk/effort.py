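"""Harmonize raw, gear-heterogeneous fishing-effort records.

Each gear reports effort in its own native units; the conversions below put
them on gear-specific standard scales that reflect how much gear is in the
water and for how long:

====================  =======================  ==================
gear                  raw units                standard unit
====================  =======================  ==================
shrimp trawl          days trawled             km trawled
bottom longline       set length, sets         km*days (soak assumed)
gillnet               set length, sets, soak   km*days (soak reported)
hook and line         lines, hours             line*days
recreational          angler trips             angler*days
====================  =======================  ==================

Trawl-day conversions use the published km/day figures (128.9 Gulf, 115.6
Atlantic) directly rather than recomputing them from speeds in knots, so
harmonized numbers match the printed constants bit-for-bit; the knots
derivation is kept as a helper.  Area- or state-level effort is spread
evenly over that area's 1-degree bins ("rasterized"), conserving totals.

All conversions are linear and homogeneous: f(c*x) = c*f(x) and f(0) = 0.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, MissingDataError
from .grid import Membership

#: km trawled per 24-h day of trawling, by basin (from typical trawl speeds
#: of 2.9 kn in the Gulf of Mexico and 2.6 kn in the Atlantic)
TRAWL_KM_PER_DAY = {"gulf": 128.9, "atlantic": 115.6}

#: assumed bottom-longline soak time: 5 hours expressed in days
LONGLINE_SOAK_DAYS = 0.2083

#: multiplier taking annual Gulf shrimping effort to the Atlantic total for
#: years before Atlantic records begin (Atlantic effort averaged 77.5% less)
ATLANTIC_BACKFILL_MULTIPLIER = 0.225

#: share of Atlantic-wide shrimping effort per sub-region (trip-based
#: weights; sum 0.999 and applied without renormalization)
ATLANTIC_SHRIMP_WEIGHTS = {"EFL": 0.085, "GA": 0.189, "SC": 0.360, "NC": 0.365}

#: alternative observer-trip-based weights (sensitivity variant)
ATLANTIC_SHRIMP_WEIGHTS_OBSERVER = {"EFL": 0.418, "GA": 0.139, "SC": 0.177, "NC": 0.266}

#: mean recreational-trip duration (hours) by state
RECREATIONAL_TRIP_HOURS = {
    "TX": 5.6,
    "LA": 4.1,
    "MS": 3.5,
    "AL": 3.4,
    "WFL": 3.9,
    "EFL": 3.8,
    "GA": 3.6,
    "SC": 3.0,
    "NC": 2.4,
    "VA": 3.2,
}

#: standard unit label per gear
STANDARD_UNITS = {
    "shrimp_trawl": "km",
    "bottom_longline": "km*days",
    "gillnet": "km*days",
    "hook_and_line": "line*days",
    "recreational": "angler*days",
}


def knots_to_km_per_day(knots: float) -> float:
    """Speed conversion helper: 1 knot = 1.852 km/h, times 24 h."""
    return knots * 1.852 * 24.0


def _check_nonneg(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise ConfigError(f"{name} must be non-negative")


def convert_trawl_effort(days_trawled, basin: str):
    """Days trawled -> km trawled using the basin's km/day constant."""
    if basin not in TRAWL_KM_PER_DAY:
        raise ConfigError(
            f"unknown basin {basin!r}; expected {sorted(TRAWL_KM_PER_DAY)}"
        )
    _check_nonneg("days_trawled", days_trawled)
    return np.asarray(days_trawled, dtype=float) * TRAWL_KM_PER_DAY[basin]


def extend_atlantic_shrimp(
    gulf_series: Mapping[int, float] | pd.Series,
    atlantic_series: Mapping[int, float] | pd.Series,
    backfill_years,
    multiplier: float = ATLANTIC_BACKFILL_MULTIPLIER,
) -> pd.Series:
    """Back-fill early Atlantic shrimping effort from the Gulf series.

    Years in ``backfill_years`` get ``multiplier * gulf(year)``; years already
    present in ``atlantic_series`` pass through unchanged.
    """
    gulf = pd.Series(dict(gulf_series), dtype=float)
    atlantic = pd.Series(dict(atlantic_series), dtype=float)
    filled = {}
    for year in backfill_years:
        if year in atlantic.index:
            continue
        if year not in gulf.index:
            raise MissingDataError(f"gulf effort missing for back-fill year {year}")
        filled[year] = multiplier * gulf[year]
    out = pd.concat([atlantic, pd.Series(filled, dtype=float)]).sort_index()
    out.index.name = "year"
    return out


def partition_atlantic_shrimp(
    atlantic_total: float,
    weights: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Split an Atlantic-wide total into sub-regions by fixed weights.

    The default trip-based weights sum to 0.999 and are applied literally,
    without renormalization.
    """
    weights = dict(ATLANTIC_SHRIMP_WEIGHTS if weights is None else weights)
    for region, w in weights.items():
        if w < 0:
            raise ConfigError(f"negative weight for {region!r}")
    _check_nonneg("atlantic_total", atlantic_total)
    return {region: atlantic_total * w for region, w in weights.items()}


def partition_gulf_latest_year(
    gulfwide_total: float,
    prior_year_by_area: Mapping[str, float],
) -> dict[str, float]:
    """Partition a Gulf-wide total using the prior year's relative distribution.

    Used when the final year reports only a basin-wide figure; shares sum to
    the input total exactly.
    """
    prior = dict(prior_year_by_area)
    total_prior = sum(prior.values())
    if total_prior <= 0:
        raise MissingDataError("prior-year distribution sums to zero")
    _check_nonneg("gulfwide_total", gulfwide_total)
    return {area: gulfwide_total * v / total_prior for area, v in prior.items()}


def longline_effort(mean_set_length_km, n_sets, soak_days: float = LONGLINE_SOAK_DAYS):
    """Bottom-longline effort in km*days (soak assumed at 5 h = 0.2083 d)."""
    _check_nonneg("set length", mean_set_length_km)
    _check_nonneg("n_sets", n_sets)
    _check_nonneg("soak_days", soak_days)
    return (
        np.asarray(mean_set_length_km, dtype=float)
        * np.asarray(n_sets, dtype=float)
        * soak_days
    )


def gillnet_effort(mean_set_length_km, n_sets, soak_days):
    """Gillnet effort in km*days with the reported soak time."""
    return longline_effort(mean_set_length_km, n_sets, soak_days=soak_days)


def hookline_effort(n_lines, hours_fished):
    """Hook-and-line effort in line*days (hours converted to days)."""
    _check_nonneg("n_lines", n_lines)
    _check_nonneg("hours_fished", hours_fished)
    return np.asarray(n_lines, dtype=float) * np.asarray(hours_fished, dtype=float) / 24.0


def recreational_effort(
    angler_trips,
    state: str,
    trip_hours: Mapping[str, float] | None = None,
):
    """Angler trips -> angler*days using the state's mean trip duration."""
    table = RECREATIONAL_TRIP_HOURS if trip_hours is None else dict(trip_hours)
    if state not in table:
        raise ConfigError(f"no trip-duration entry for state {state!r}")
    _check_nonneg("angler_trips", angler_trips)
    return np.asarray(angler_trips, dtype=float) * table[state] / 24.0


def rasterize_effort(
    area_effort: pd.DataFrame,
    membership: Membership,
) -> pd.DataFrame:
    """Spread area-level effort evenly over each area's member bins.

    ``area_effort`` columns: gear, year, area_label, effort, unit.  Each bin
    of an n-bin area receives effort/n, so area totals are conserved; a
    one-bin area passes through unchanged.  Returns one row per
    (gear, year, bin).
    """
    required = {"gear", "year", "area_label", "effort", "unit"}
    missing = required - set(area_effort.columns)
    if missing:
        raise ConfigError(f"area effort table lacks columns {sorted(missing)}")
    rows = []
    for rec in area_effort.itertuples(index=False):
        label = str(rec.area_label)
        if label not in membership:
            raise ConfigError(f"area label {label!r} has no bin membership")
        bins = membership[label]
        share = float(rec.effort) / len(bins)
        for blat, blon in bins:
            rows.append(
                {
                    "gear": rec.gear,
                    "year": int(rec.year),
                    "bin_lat": blat,
                    "bin_lon": blon,
                    "effort": share,
                    "unit": rec.unit,
                }
            )
    out = pd.DataFrame(
        rows, columns=["gear", "year", "bin_lat", "bin_lon", "effort", "unit"]
    )
    # a bin may belong to several overlapping labels of the same gear
    return (
        out.groupby(["gear", "year", "bin_lat", "bin_lon", "unit"], as_index=False)[
            "effort"
        ]
        .sum()[["gear", "year", "bin_lat", "bin_lon", "effort", "unit"]]
        .sort_values(["gear", "year", "bin_lat", "bin_lon"])
        .reset_index(drop=True)
    )


def harmonize_gear_table(raw: pd.DataFrame, gear: str) -> pd.DataFrame:
    """Convert one gear's raw records into area-level standard units.

    ``raw`` carries gear-specific quantity columns (see module table); the
    result has columns (gear, year, area_label, effort, unit) ready for
    :func:`rasterize_effort`.
    """
    if gear == "shrimp_trawl":
        effort = np.array(
            [
                float(convert_trawl_effort(d, basin=b))
                for d, b in zip(raw["days_trawled"], raw["basin"])
            ]
        )
    elif gear == "bottom_longline":
        effort = longline_effort(
            raw["mean_set_length_km"].to_numpy(), raw["n_sets"].to_numpy()
        )
    elif gear == "gillnet":
        effort = gillnet_effort(
            raw["mean_set_length_km"].to_numpy(),
            raw["n_sets"].to_numpy(),
            raw["soak_days"].to_numpy(),
        )
    elif gear == "hook_and_line":
        effort = hookline_effort(
            raw["n_lines"].to_numpy(), raw["hours_fished"].to_numpy()
        )
    elif gear == "recreational":
        effort = np.array(
            [
                recreational_effort(t, s)
                for t, s in zip(raw["angler_trips"], raw["area_label"])
            ]
        )
    else:
        raise ConfigError(f"unknown gear {gear!r}")
    return pd.DataFrame(
        {
            "gear": gear,
            "year": raw["year"].astype(int).to_numpy(),
            "area_label": raw["area_label"].astype(str).to_numpy(),
            "effort": effort,
            "unit": STANDARD_UNITS[gear],
        }
    )


def harmonize_effort(
    raw_tables: Mapping[str, pd.DataFrame],
    membership: Membership,
) -> pd.DataFrame:
    """Full harmonization: per-gear unit conversion then binning.

    ``raw_tables`` maps gear name -> raw records table.  Returns the
    harmonized per-bin-per-year effort table (gear, year, bin_lat, bin_lon,
    effort, unit).
    """
    parts = [harmonize_gear_table(tbl, gear) for gear, tbl in raw_tables.items()]
    area_level = pd.concat(parts, ignore_index=True)
    return rasterize_effort(area_level, membership)
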