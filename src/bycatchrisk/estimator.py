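"""Bycatch-rate estimation, risk indices, and extrapolated totals.

For every spatial unit (1-degree bin, or state/area for records only known
at that level) with observed bycatch, the minimum bycatch rate is

    q = T_b / (T_p * F)

where T_b is the observed count, T_p the modelled turtle abundance and F
the harmonized fishing effort in that unit-year.  Units without observed
bycatch contribute no rate (all bycatch in a unit is assumed observed, so
each q is a floor, not an unbiased estimate).  Rates for a species-gear are
summarized by their geometric mean, bracketed by the geometric means of the
rates below and above it — the convention used to report uncertainty, with
"--" where a bracket set is empty.

Extrapolation multiplies the summary rate by the summed annual risk index
R = T_p * F over all bins:  B_y = GM * sum_bins R(bin, y), and percent of
population is 100 * sum_gears B_y / sum_bins T_p(bin, y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConfigError, DataError
from .grid import Membership


@dataclass(frozen=True)
class RateSummary:
    """Geometric-mean bycatch rate for one species-gear, with GM brackets.

    ``lower``/``upper`` are the geometric means of rates strictly below /
    above the overall geometric mean; ``None`` (rendered "--") when that
    partition is empty, as happens for singleton rate sets.
    """

    species: str
    gear: str
    n: int
    gm: float
    lower: float | None
    upper: float | None

    def bound(self, which: str) -> float:
        """The lower/upper/central rate, falling back to the GM when a
        bracket is undefined."""
        if which == "central":
            return self.gm
        value = {"lower": self.lower, "upper": self.upper}[which]
        return self.gm if value is None else value

    @staticmethod
    def _fmt(x: float | None) -> str:
        return "--" if x is None else f"{x:.3g}"

    def __str__(self) -> str:
        return (
            f"{self.species}/{self.gear}: {self.gm:.3g} "
            f"({self._fmt(self.lower)}-{self._fmt(self.upper)}), n={self.n}"
        )


def geometric_mean(values) -> float:
    """exp(mean(ln x)) of strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DataError("geometric mean of an empty set")
    if np.any(arr <= 0):
        raise DataError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def compute_rates(
    bycatch: pd.DataFrame,
    abundance: pd.DataFrame,
    effort: pd.DataFrame,
    membership: Membership | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit-year bycatch rates q = T_b/(T_p*F) for observed bycatch.

    ``bycatch`` rows identify location either by (bin_lat, bin_lon) or by
    ``area_label`` (recreational records are typically state-level); area
    records use T_p and F summed over the area's member bins, which requires
    ``membership``.  ``abundance`` is the aggregated (species, year, bin_lat,
    bin_lon, t_p) table; ``effort`` the harmonized (gear, year, bin_lat,
    bin_lon, effort) table.

    Zero-count records never yield rates.  Records with T_b > 0 but
    T_p*F = 0 (or no matching abundance/effort row) are returned separately
    as excluded records, never silently dropped.

    Returns ``(rates, excluded)``.
    """
    tp = abundance.set_index(["species", "year", "bin_lat", "bin_lon"])["t_p"]
    f = effort.set_index(["gear", "year", "bin_lat", "bin_lon"])["effort"]
    rates = []
    excluded = []
    for rec in bycatch.itertuples(index=False):
        t_b = int(rec.count)
        if t_b < 0:
            raise DataError("negative bycatch count")
        if t_b == 0:
            continue
        year = int(rec.year)
        has_bin = (
            hasattr(rec, "bin_lat")
            and not pd.isna(rec.bin_lat)
            and hasattr(rec, "bin_lon")
            and not pd.isna(rec.bin_lon)
        )
        if has_bin:
            bins = [(int(rec.bin_lat), int(rec.bin_lon))]
            unit = f"bin({bins[0][0]},{bins[0][1]})"
        else:
            label = str(getattr(rec, "area_label", ""))
            if membership is None or label not in (membership or {}):
                raise AlignmentError(
                    f"bycatch record at area {label!r} has no bin membership"
                )
            bins = membership[label]
            unit = label
        t_p = sum(tp.get((rec.species, year, bl, bn), 0.0) for bl, bn in bins)
        f_val = sum(f.get((rec.gear, year, bl, bn), 0.0) for bl, bn in bins)
        base = {
            "species": rec.species,
            "gear": rec.gear,
            "year": year,
            "unit": unit,
            "t_b": t_b,
            "t_p": t_p,
            "effort": f_val,
        }
        if t_p > 0 and f_val > 0:
            rates.append({**base, "rate": t_b / (t_p * f_val)})
        else:
            excluded.append({**base, "reason": "t_p or effort is zero"})
    cols = ["species", "gear", "year", "unit", "t_b", "t_p", "effort"]
    return (
        pd.DataFrame(rates, columns=cols + ["rate"]),
        pd.DataFrame(excluded, columns=cols + ["reason"]),
    )


def summarize_rates(rates: pd.DataFrame) -> list[RateSummary]:
    """Geometric-mean rate per species-gear with strict-inequality brackets.

    Rates equal to the GM belong to neither bracket (equality is taken up
    to 1e-12 relative, so that a singleton or an all-equal set — whose GM
    round-trips through log space with float error — yields no brackets).
    Species-gear groups with no rates simply do not appear (the gear is
    dropped from the summary, as for a gear with no observed bycatch).
    """
    out = []
    for (species, gear), grp in rates.groupby(["species", "gear"], sort=True):
        q = grp["rate"].to_numpy(dtype=float)
        gm = geometric_mean(q)
        tie = np.isclose(q, gm, rtol=1e-12, atol=0.0)
        below = q[(q < gm) & ~tie]
        above = q[(q > gm) & ~tie]
        out.append(
            RateSummary(
                species=species,
                gear=gear,
                n=q.size,
                gm=gm,
                lower=geometric_mean(below) if below.size else None,
                upper=geometric_mean(above) if above.size else None,
            )
        )
    return out


def summary_table(summaries: list[RateSummary]) -> pd.DataFrame:
    """Rate-summary table with "--" for undefined brackets."""
    return pd.DataFrame(
        [
            {
                "species": s.species,
                "gear": s.gear,
                "n": s.n,
                "gm_rate": s.gm,
                "lower": "--" if s.lower is None else s.lower,
                "upper": "--" if s.upper is None else s.upper,
            }
            for s in summaries
        ]
    )


def risk_indices(abundance: pd.DataFrame, effort: pd.DataFrame) -> pd.DataFrame:
    """Risk index R = T_p * F per (species, gear, year, bin).

    Only bins where both factors exist and are positive carry risk; the
    result is the exposure base over which summary rates are extrapolated.
    """
    merged = abundance.merge(effort, on=["year", "bin_lat", "bin_lon"], how="inner")
    merged["risk"] = merged["t_p"] * merged["effort"]
    return merged[
        ["species", "gear", "year", "bin_lat", "bin_lon", "t_p", "effort", "risk"]
    ]


def risk_map(risk: pd.DataFrame, years=None) -> pd.DataFrame:
    """Multi-year mean risk per bin with its log10 (for mapping).

    ``log10_risk`` is left missing where the mean risk is zero.
    """
    sub = risk if years is None else risk[risk["year"].isin(list(years))]
    out = sub.groupby(["species", "gear", "bin_lat", "bin_lon"], as_index=False)[
        "risk"
    ].mean()
    with np.errstate(divide="ignore"):
        out["log10_risk"] = np.where(out["risk"] > 0, np.log10(out["risk"]), np.nan)
    return out


def extrapolate_bycatch(
    summaries: list[RateSummary], risk: pd.DataFrame
) -> pd.DataFrame:
    """Annual total bycatch B_y = rate * sum_bins R(bin, y) per species-gear.

    Central, lower and upper variants use the GM and its brackets (bracket
    falling back to the GM where undefined).
    """
    annual_risk = risk.groupby(["species", "gear", "year"], as_index=False)[
        "risk"
    ].sum()
    rows = []
    for s in summaries:
        sub = annual_risk[
            (annual_risk["species"] == s.species) & (annual_risk["gear"] == s.gear)
        ]
        for rec in sub.itertuples(index=False):
            rows.append(
                {
                    "species": s.species,
                    "gear": s.gear,
                    "year": int(rec.year),
                    "bycatch": s.gm * rec.risk,
                    "bycatch_lower": s.bound("lower") * rec.risk,
                    "bycatch_upper": s.bound("upper") * rec.risk,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["species", "gear", "year", "bycatch", "bycatch_lower", "bycatch_upper"],
    )


def annual_summary(estimates: pd.DataFrame) -> pd.DataFrame:
    """Geometric mean over years of annual bycatch per species-gear.

    Years with zero estimated bycatch (no effort overlap) are excluded from
    the geometric mean rather than zeroing it out; a species-gear with no
    positive year reports NaN.
    """
    rows = []
    for (species, gear), grp in estimates.groupby(["species", "gear"], sort=True):
        b = grp["bycatch"].to_numpy(dtype=float)
        pos = b[b > 0]
        rows.append(
            {
                "species": species,
                "gear": gear,
                "n_years": int(pos.size),
                "gm_annual_bycatch": geometric_mean(pos) if pos.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def percent_of_population(
    estimates: pd.DataFrame, abundance: pd.DataFrame, gears=None
) -> pd.DataFrame:
    """P_y = 100 * sum_gears B_y / N_y with N_y the coastal population.

    ``gears`` restricts the numerator (e.g. shrimp-trawl-only series);
    default sums all gears present.
    """
    sub = estimates if gears is None else estimates[estimates["gear"].isin(gears)]
    b = sub.groupby(["species", "year"], as_index=False)["bycatch"].sum()
    n = abundance.groupby(["species", "year"], as_index=False)["t_p"].sum()
    merged = b.merge(n, on=["species", "year"], how="inner")
    if len(merged) < len(b):
        raise AlignmentError("abundance missing for some estimate years")
    merged["percent"] = 100.0 * merged["bycatch"] / merged["t_p"]
    return merged[["species", "year", "bycatch", "t_p", "percent"]]


def trend_test(series: pd.Series | dict) -> dict:
    """Pearson correlation of an annual series against year.

    Returns {"r", "p", "n"}; a constant series (zero variance) has an
    undefined correlation and reports r = p = NaN.
    """
    s = pd.Series(dict(series) if isinstance(series, dict) else series).sort_index()
    years = s.index.to_numpy(dtype=float)
    vals = s.to_numpy(dtype=float)
    n = vals.size
    if n < 3:
        raise DataError("trend test needs at least 3 years")
    if np.ptp(vals) == 0 or np.ptp(years) == 0:
        return {"r": np.nan, "p": np.nan, "n": n}
    r, p = stats.pearsonr(years, vals)
    return {"r": float(r), "p": float(p), "n": n}


def rate_trend_check(rates: pd.DataFrame) -> pd.DataFrame:
    """OLS of ln(rate) on year per species-gear: R^2, p, n.

    Screens for temporal trend in bycatch rates (a trend would argue against
    pooling years into a single geometric mean).  Log scale, consistent with
    the geometric-mean aggregation; recorded in the ``scale`` column.
    """
    rows = []
    for (species, gear), grp in rates.groupby(["species", "gear"], sort=True):
        q = grp["rate"].to_numpy(dtype=float)
        years = grp["year"].to_numpy(dtype=float)
        n = q.size
        if n < 3 or np.ptp(years) == 0:
            rows.append(
                {"species": species, "gear": gear, "r2": np.nan, "p": np.nan,
                 "n": n, "scale": "ln"}
            )
            continue
        lnq = np.log(q)
        if np.ptp(lnq) == 0:
            rows.append(
                {"species": species, "gear": gear, "r2": 0.0, "p": 1.0,
                 "n": n, "scale": "ln"}
            )
            continue
        res = stats.linregress(years, lnq)
        rows.append(
            {
                "species": species,
                "gear": gear,
                "r2": float(res.rvalue**2),
                "p": float(res.pvalue),
                "n": n,
                "scale": "ln",
            }
        )
    return pd.DataFrame(rows)


def assemble_observer_series(raw: pd.DataFrame, n_fill_years: int = 3) -> pd.DataFrame:
    """Sum observer-program estimates over basins and net classes per year.

    ``raw`` columns: species, year, basin, net_class, median, ci_low,
    ci_high.  A basin missing its final year(s) relative to the overall
    span is filled with the mean of that basin's previous ``n_fill_years``
    (applied to median and CI bounds alike) before summing; fewer than
    ``n_fill_years`` prior years is a missing-data error.
    """
    need = {"species", "year", "basin", "net_class", "median", "ci_low", "ci_high"}
    if not need.issubset(raw.columns):
        raise ConfigError(f"observer series needs columns {sorted(need)}")
    if np.any(raw["ci_low"] > raw["median"]) or np.any(raw["median"] > raw["ci_high"]):
        raise DataError("observer series CI must bracket the median")
    out_rows = []
    for species, sp in raw.groupby("species"):
        years = np.arange(sp["year"].min(), sp["year"].max() + 1)
        # collapse net classes within basin-year first
        basin_year = sp.groupby(["basin", "year"], as_index=False)[
            ["median", "ci_low", "ci_high"]
        ].sum()
        filled = []
        for basin, grp in basin_year.groupby("basin"):
            grp = grp.set_index("year").sort_index()
            for y in years:
                if y in grp.index:
                    filled.append(
                        {"basin": basin, "year": int(y), **grp.loc[y][
                            ["median", "ci_low", "ci_high"]
                        ].to_dict()}
                    )
                else:
                    prior = [y - k for k in range(1, n_fill_years + 1)]
                    if not all(p in grp.index for p in prior):
                        raise DataError(
                            f"cannot fill {basin} {y}: need {n_fill_years} prior years"
                        )
                    mean = grp.loc[prior, ["median", "ci_low", "ci_high"]].mean()
                    filled.append({"basin": basin, "year": int(y), **mean.to_dict()})
                    grp.loc[y] = mean  # allow cascading fills
                    grp = grp.sort_index()
        fdf = pd.DataFrame(filled)
        total = fdf.groupby("year", as_index=False)[["median", "ci_low", "ci_high"]].sum()
        total.insert(0, "species", species)
        out_rows.append(total)
    return pd.concat(out_rows, ignore_index=True)
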