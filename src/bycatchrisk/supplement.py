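"""Reader for the supplementary-spreadsheet layout of risk and bycatch data.

The workbook layout: a "Bycatch" sheet listing observed bycatch (species,
gear, year, area, count), and one risk sheet per fishery ("Shrimp_Risk",
"Rec_Risk", "BLL_Risk", "Gillnet_Risk", "H&L_Risk") holding risk indices
R = T_p * F by species and year.  Risk-sheet columns are either named areas
(GOM_Area_1..4, state codes, GOM_Z1..Z21) or four-digit headers encoding a
1-degree bin centre: first two digits latitude (degrees N), last two
longitude (degrees W), e.g. "2889" = 28.5 N, 89.5 W -> bin (28, -89).

Because the risk index is exactly the rate denominator, observed counts
joined to risk cells give rates q = T_b / R directly, from which the whole
summary/extrapolation chain can be reproduced deterministically.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimator
from .errors import DataError

RISK_SHEETS = {
    "Shrimp_Risk": "shrimp_trawl",
    "Rec_Risk": "recreational",
    "BLL_Risk": "bottom_longline",
    "Gillnet_Risk": "gillnet",
    "H&L_Risk": "hook_and_line",
}

_BIN_HEADER = re.compile(r"^(\d{2})(\d{2})$")


def parse_bin_header(header: str) -> tuple[int, int] | None:
    """Decode a latitude/longitude digit-pair column header, if it is one.

    Returns the (bin_lat, bin_lon) of the 1-degree bin whose centre the
    header encodes (west longitude stored negative), or None for named-area
    headers.
    """
    m = _BIN_HEADER.match(str(header).strip())
    if not m:
        return None
    lat_c, lon_w = int(m.group(1)), int(m.group(2))
    return (lat_c, -lon_w)


def read_bycatch_sheet(path: str | Path, sheet: str = "Bycatch") -> pd.DataFrame:
    """Observed-bycatch records: species, gear, year, area, count."""
    df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    df.columns = [str(c).strip().lower() for c in df.columns]
    need = {"species", "gear", "year", "area", "count"}
    if not need.issubset(df.columns):
        raise DataError(f"sheet {sheet!r} lacks columns {sorted(need - set(df.columns))}")
    df["year"] = df["year"].astype(int)
    df["count"] = df["count"].astype(int)
    return df[["species", "gear", "year", "area", "count"]]


def read_risk_sheet(path: str | Path, sheet: str) -> pd.DataFrame:
    """One fishery's risk-index sheet in tidy form.

    Returns (species, gear, year, area, bin_lat, bin_lon, risk); bin
    columns are NaN for named-area columns.
    """
    if sheet not in RISK_SHEETS:
        raise DataError(f"unknown risk sheet {sheet!r}")
    wide = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    wide.columns = [str(c).strip() for c in wide.columns]
    id_cols = {c.lower(): c for c in wide.columns}
    if "species" not in id_cols or "year" not in id_cols:
        raise DataError(f"sheet {sheet!r} needs Species and Year columns")
    rows = []
    for rec in wide.itertuples(index=False):
        rec_d = dict(zip(wide.columns, rec))
        species = rec_d[id_cols["species"]]
        year = int(rec_d[id_cols["year"]])
        for col, value in rec_d.items():
            if col in (id_cols["species"], id_cols["year"]) or pd.isna(value):
                continue
            b = parse_bin_header(col)
            rows.append(
                {
                    "species": species,
                    "gear": RISK_SHEETS[sheet],
                    "year": year,
                    "area": col,
                    "bin_lat": b[0] if b else np.nan,
                    "bin_lon": b[1] if b else np.nan,
                    "risk": float(value),
                }
            )
    return pd.DataFrame(
        rows, columns=["species", "gear", "year", "area", "bin_lat", "bin_lon", "risk"]
    )


def read_all_risk(path: str | Path, sheets=None) -> pd.DataFrame:
    """Concatenate every available risk sheet in a workbook."""
    available = pd.ExcelFile(path, engine="openpyxl").sheet_names
    wanted = list(RISK_SHEETS if sheets is None else sheets)
    parts = [read_risk_sheet(path, s) for s in wanted if s in available]
    if not parts:
        raise DataError(f"no risk sheets found in {path}")
    return pd.concat(parts, ignore_index=True)


def estimate_from_supplement(path: str | Path) -> dict:
    """Reproduce the rate/extrapolation chain from a supplement workbook.

    Joins observed counts to risk cells by (species, gear, year, area),
    forms rates q = count / R, summarizes per species-gear, extrapolates
    B_y = GM * sum_area R(area, y), and reports the geometric mean of the
    annual totals.  Returns {"rates", "summaries", "summary", "estimates",
    "annual"}.
    """
    bycatch = read_bycatch_sheet(path)
    risk = read_all_risk(path)
    risk_idx = risk.set_index(["species", "gear", "year", "area"])["risk"]
    rate_rows = []
    for rec in bycatch.itertuples(index=False):
        if rec.count <= 0:
            continue
        key = (rec.species, rec.gear, rec.year, str(rec.area))
        if key not in risk_idx.index:
            raise DataError(f"no risk cell for bycatch record {key}")
        r = float(risk_idx.loc[key])
        if r <= 0:
            continue  # bycatch with zero modelled exposure: no defined rate
        rate_rows.append(
            {
                "species": rec.species,
                "gear": rec.gear,
                "year": int(rec.year),
                "unit": str(rec.area),
                "rate": rec.count / r,
            }
        )
    rates = pd.DataFrame(rate_rows)
    summaries = estimator.summarize_rates(rates)
    annual_risk = risk.groupby(["species", "gear", "year"], as_index=False)["risk"].sum()
    est_rows = []
    for s in summaries:
        sub = annual_risk[
            (annual_risk["species"] == s.species) & (annual_risk["gear"] == s.gear)
        ]
        for rec in sub.itertuples(index=False):
            est_rows.append(
                {
                    "species": s.species,
                    "gear": s.gear,
                    "year": int(rec.year),
                    "bycatch": s.gm * rec.risk,
                    "bycatch_lower": s.bound("lower") * rec.risk,
                    "bycatch_upper": s.bound("upper") * rec.risk,
                }
            )
    estimates = pd.DataFrame(
        est_rows,
        columns=["species", "gear", "year", "bycatch", "bycatch_lower", "bycatch_upper"],
    )
    return {
        "rates": rates,
        "summaries": summaries,
        "summary": estimator.summary_table(summaries),
        "estimates": estimates,
        "annual": estimator.annual_summary(estimates),
    }
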