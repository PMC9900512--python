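"""Lagrangian particle advection through gridded surface-velocity fields.

Particles are integrated with classical fourth-order Runge-Kutta at a fixed
step (default half an hour), sampling the velocity field bilinearly in space
and linearly in time.  Positions are kept in degrees; velocities (m/s) are
converted to deg/day through an equirectangular projection with a fixed
reference latitude, so a spatially uniform flow produces exactly linear
motion.

Particles that step off the grid (in the synthetic world, the western edge
plays the part of the coastline) are frozen at their last in-grid position
and flagged — never dropped — so the particle budget is conserved at every
step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .errors import ConfigError, DataError
from .flows import M_PER_DEG


@dataclass
class TrajectorySet:
    """Positions and bookkeeping for a batch of particles from one release.

    ``lon_at_age``/``lat_at_age`` have shape (n_ages, n_particles) and hold
    the position at the stored step nearest each requested age; ``frozen``
    marks particles that left the grid (position is where they froze).
    """

    release_lon: np.ndarray
    release_lat: np.ndarray
    release_day: np.ndarray
    ages_days: np.ndarray
    lon_at_age: np.ndarray
    lat_at_age: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    frozen: np.ndarray
    step_days: float
    path_times: np.ndarray | None = None
    path_lon: np.ndarray | None = None  # (n_stored, n_particles)
    path_lat: np.ndarray | None = None

    @property
    def n_particles(self) -> int:
        return self.release_lon.size


class _VelocityField:
    """Bilinear-in-space, linear-in-time sampler returning deg/day tendencies."""

    def __init__(self, ds: xr.Dataset):
        self.lats = np.asarray(ds["lat"].values, dtype=float)
        self.lons = np.asarray(ds["lon"].values, dtype=float)
        self.times = np.atleast_1d(np.asarray(ds["time"].values, dtype=float))
        self.u = np.asarray(ds["u"].values, dtype=float).reshape(
            self.times.size, self.lats.size, self.lons.size
        )
        self.v = np.asarray(ds["v"].values, dtype=float).reshape(self.u.shape)
        if self.lats.size < 2 or self.lons.size < 2:
            raise ConfigError("velocity grid needs at least 2 nodes per axis")
        self.dlat = self.lats[1] - self.lats[0]
        self.dlon = self.lons[1] - self.lons[0]
        mid_lat = 0.5 * (self.lats[0] + self.lats[-1])
        self.m_lon = M_PER_DEG * np.cos(np.deg2rad(mid_lat))
        self.m_lat = M_PER_DEG

    @property
    def lat_bounds(self) -> tuple[float, float]:
        return float(self.lats[0]), float(self.lats[-1])

    @property
    def lon_bounds(self) -> tuple[float, float]:
        return float(self.lons[0]), float(self.lons[-1])

    def check_coverage(self, t0: float, t1: float) -> None:
        if self.times.size == 1:
            return  # stationary field: valid for all times
        if t0 < self.times[0] - 1e-9 or t1 > self.times[-1] + 1e-9:
            raise DataError(
                f"velocity field covers days [{self.times[0]}, {self.times[-1]}] "
                f"but drift needs [{t0}, {t1}]"
            )

    def _field_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        if self.times.size == 1:
            return self.u[0], self.v[0]
        k = np.searchsorted(self.times, t, side="right") - 1
        k = min(max(k, 0), self.times.size - 2)
        w = (t - self.times[k]) / (self.times[k + 1] - self.times[k])
        w = min(max(w, 0.0), 1.0)
        return (
            (1 - w) * self.u[k] + w * self.u[k + 1],
            (1 - w) * self.v[k] + w * self.v[k + 1],
        )

    def tendency(
        self, lon: np.ndarray, lat: np.ndarray, t: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """d(lon)/dt, d(lat)/dt in deg/day at the given positions.

        Positions are clamped to the grid for sampling (intermediate RK
        stages may momentarily poke past the edge); whether a particle is
        frozen is decided by the stepper on the full-step position.
        """
        ut, vt = self._field_at(t)
        fi = np.clip((lat - self.lats[0]) / self.dlat, 0.0, self.lats.size - 1 - 1e-12)
        fj = np.clip((lon - self.lons[0]) / self.dlon, 0.0, self.lons.size - 1 - 1e-12)
        i = fi.astype(int)
        j = fj.astype(int)
        wi = fi - i
        wj = fj - j
        u = (
            ut[i, j] * (1 - wi) * (1 - wj)
            + ut[i + 1, j] * wi * (1 - wj)
            + ut[i, j + 1] * (1 - wi) * wj
            + ut[i + 1, j + 1] * wi * wj
        )
        v = (
            vt[i, j] * (1 - wi) * (1 - wj)
            + vt[i + 1, j] * wi * (1 - wj)
            + vt[i, j + 1] * (1 - wi) * wj
            + vt[i + 1, j + 1] * wi * wj
        )
        sec_per_day = 86400.0
        return u * sec_per_day / self.m_lon, v * sec_per_day / self.m_lat


def advect_particles(
    velocity: xr.Dataset,
    release_lon: np.ndarray,
    release_lat: np.ndarray,
    release_day: np.ndarray,
    duration_days: float,
    ages_days: np.ndarray | list[float] | None = None,
    step_hours: float = 0.5,
    store_every: int | None = None,
) -> TrajectorySet:
    """Integrate particles through a velocity field with RK4.

    Each particle starts at its release position on its release day and is
    tracked for ``duration_days``.  ``ages_days`` lists ages (days since
    release) at which positions are recorded — each is snapped to the
    nearest integration step.  ``store_every`` additionally keeps the full
    path every k-th step (for diagnostics/tests; memory scales with it).
    """
    release_lon = np.atleast_1d(np.asarray(release_lon, dtype=float))
    release_lat = np.atleast_1d(np.asarray(release_lat, dtype=float))
    release_day = np.broadcast_to(
        np.atleast_1d(np.asarray(release_day, dtype=float)), release_lon.shape
    ).copy()
    if release_lon.shape != release_lat.shape:
        raise ConfigError("release_lon and release_lat must have the same shape")
    if duration_days <= 0:
        raise ConfigError("duration_days must be positive")

    fld = _VelocityField(velocity)
    la0, la1 = fld.lat_bounds
    lo0, lo1 = fld.lon_bounds
    inside = (
        (release_lat >= la0)
        & (release_lat <= la1)
        & (release_lon >= lo0)
        & (release_lon <= lo1)
    )
    if not inside.all():
        raise ConfigError("release points must lie inside the velocity grid")

    h = step_hours / 24.0
    t_start = float(release_day.min())
    t_end = float(release_day.max()) + duration_days
    fld.check_coverage(t_start, t_end)

    ages = np.asarray([] if ages_days is None else ages_days, dtype=float)
    if np.any(ages > duration_days + 1e-9):
        raise ConfigError("requested age exceeds drift duration")
    age_steps = np.rint(ages / h).astype(int)  # nearest stored step per age

    n = release_lon.size
    n_steps = int(np.ceil((t_end - t_start) / h - 1e-9))
    rel_step = np.rint((release_day - t_start) / h).astype(int)
    dur_steps = int(np.rint(duration_days / h))

    lon = release_lon.copy()
    lat = release_lat.copy()
    frozen = np.zeros(n, dtype=bool)
    lon_at_age = np.full((ages.size, n), np.nan)
    lat_at_age = np.full((ages.size, n), np.nan)

    # record age-0-step positions (covers age_steps == 0 and late snaps)
    for a_idx in range(ages.size):
        sel = age_steps[a_idx] == 0
        lon_at_age[a_idx, sel] = lon[sel]
        lat_at_age[a_idx, sel] = lat[sel]

    path_t: list[float] = []
    path_lon: list[np.ndarray] = []
    path_lat: list[np.ndarray] = []
    if store_every is not None:
        path_t.append(t_start)
        path_lon.append(lon.copy())
        path_lat.append(lat.copy())

    for step in range(n_steps):
        t = t_start + step * h
        age_step = step - rel_step  # steps completed since release, per particle
        active = (age_step >= 0) & (age_step < dur_steps) & ~frozen
        if active.any():
            al = lon[active]
            aa = lat[active]
            k1u, k1v = fld.tendency(al, aa, t)
            k2u, k2v = fld.tendency(al + 0.5 * h * k1u, aa + 0.5 * h * k1v, t + 0.5 * h)
            k3u, k3v = fld.tendency(al + 0.5 * h * k2u, aa + 0.5 * h * k2v, t + 0.5 * h)
            k4u, k4v = fld.tendency(al + h * k3u, aa + h * k3v, t + h)
            new_lon = al + (h / 6.0) * (k1u + 2 * k2u + 2 * k3u + k4u)
            new_lat = aa + (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
            out = (
                (new_lat < la0) | (new_lat > la1) | (new_lon < lo0) | (new_lon > lo1)
            ) | ~(np.isfinite(new_lon) & np.isfinite(new_lat))
            idx = np.flatnonzero(active)
            ok = idx[~out]
            lon[ok] = new_lon[~out]
            lat[ok] = new_lat[~out]
            frozen[idx[out]] = True  # freeze at last in-grid position

        done_steps = step + 1 - rel_step
        for a_idx in range(ages.size):
            sel = done_steps == age_steps[a_idx]
            if sel.any():
                lon_at_age[a_idx, sel] = lon[sel]
                lat_at_age[a_idx, sel] = lat[sel]

        if store_every is not None and (step + 1) % store_every == 0:
            path_t.append(t_start + (step + 1) * h)
            path_lon.append(lon.copy())
            path_lat.append(lat.copy())

    return TrajectorySet(
        release_lon=release_lon,
        release_lat=release_lat,
        release_day=release_day,
        ages_days=ages,
        lon_at_age=lon_at_age,
        lat_at_age=lat_at_age,
        lon=lon,
        lat=lat,
        frozen=frozen,
        step_days=h,
        path_times=np.asarray(path_t) if store_every is not None else None,
        path_lon=np.asarray(path_lon) if store_every is not None else None,
        path_lat=np.asarray(path_lat) if store_every is not None else None,
    )
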