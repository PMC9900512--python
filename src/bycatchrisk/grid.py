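"""1°x1° analysis grid and area-to-bin membership tables.

Bins are identified by the integer pair ``(floor(lat), floor(lon))`` and
cover the half-open square ``[lat, lat+1) x [lon, lon+1)``, so every point
belongs to exactly one bin.  Area labels (states, statistical zones, basin
sub-regions) map onto sets of bins through a membership table supplied as
configuration data, which lets the synthetic world define its own geography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError

#: integer (floor(lat), floor(lon)) pair identifying a 1-degree bin
BinId = tuple[int, int]

#: area label -> list of member bins
Membership = dict[str, list[BinId]]


@dataclass(frozen=True)
class Grid:
    """Regular 1-degree grid spanning ``[lat0, lat0+nlat) x [lon0, lon0+nlon)``.

    Velocity fields are defined on the (nlat+1) x (nlon+1) integer-degree
    nodes; particles and abundance live in the nlat x nlon cells.
    """

    lat0: int
    lon0: int
    nlat: int
    nlon: int

    def __post_init__(self) -> None:
        if self.nlat < 1 or self.nlon < 1:
            raise ConfigError("grid must contain at least one cell per axis")

    @property
    def lat_max(self) -> int:
        return self.lat0 + self.nlat

    @property
    def lon_max(self) -> int:
        return self.lon0 + self.nlon

    def contains(self, lat: float, lon: float) -> bool:
        return (self.lat0 <= lat < self.lat_max) and (self.lon0 <= lon < self.lon_max)

    def bin_of(self, lat: float, lon: float) -> BinId:
        """Bin containing a point; raises if the point is off-grid."""
        if not self.contains(lat, lon):
            raise ConfigError(f"point ({lat}, {lon}) outside grid")
        return (math.floor(lat), math.floor(lon))

    def bins(self) -> list[BinId]:
        return [
            (self.lat0 + i, self.lon0 + j)
            for i in range(self.nlat)
            for j in range(self.nlon)
        ]

    @property
    def mid_lat(self) -> float:
        """Reference latitude of the equirectangular projection used for advection."""
        return self.lat0 + self.nlat / 2.0


def membership_to_frame(membership: Mapping[str, Iterable[BinId]]) -> pd.DataFrame:
    rows = [
        {"area_label": label, "bin_lat": b[0], "bin_lon": b[1]}
        for label, bins in membership.items()
        for b in bins
    ]
    return pd.DataFrame(rows, columns=["area_label", "bin_lat", "bin_lon"])


def membership_from_frame(frame: pd.DataFrame) -> Membership:
    """Parse an (area_label, bin_lat, bin_lon) table into a membership map."""
    required = {"area_label", "bin_lat", "bin_lon"}
    if not required.issubset(frame.columns):
        raise ConfigError(f"membership table needs columns {sorted(required)}")
    out: Membership = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.area_label), []).append(
            (int(row.bin_lat), int(row.bin_lon))
        )
    return out


def validate_membership(membership: Membership, grid: Grid | None = None) -> None:
    """Every label maps to >=1 bin; bins are on-grid when a grid is given."""
    for label, bins in membership.items():
        if not bins:
            raise ConfigError(f"area {label!r} has no member bins")
        if grid is not None:
            for lat, lon in bins:
                if not grid.contains(lat + 0.5, lon + 0.5):
                    raise ConfigError(f"area {label!r} bin ({lat}, {lon}) off-grid")
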