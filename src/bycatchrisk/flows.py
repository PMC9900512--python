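"""Analytic surface-velocity fields and their sampling onto a grid.

Three named flows are available, chosen because each admits an exact or
high-accuracy reference solution for trajectory tests:

``uniform``
    Constant ``(u, v)`` everywhere — trajectories are straight lines.
``solid_rotation``
    Solid-body rotation about a centre; trajectories are circles of
    conserved radius with a closed-form period ``2*pi/omega``.
``double_gyre``
    The classic two-gyre stream-function flow on the grid's bounding box;
    divergence-free by construction, time-periodic when ``eps > 0``.

Velocities are in m/s.  Stream-function flows are defined in the projected
metre coordinates of the grid (equirectangular, fixed reference latitude),
the same projection the advection kernel integrates in.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import xarray as xr

from .errors import ConfigError
from .grid import Grid

#: metres per degree of latitude (and of longitude at the reference latitude,
#: after the cos(lat_ref) scaling)
M_PER_DEG = 111_320.0

#: (lon_deg, lat_deg, t_days) -> (u, v) in m/s, vectorised over arrays
FlowFunc = Callable[[np.ndarray, np.ndarray, float], tuple[np.ndarray, np.ndarray]]

FLOW_NAMES = ("uniform", "solid_rotation", "double_gyre")


def projection_scales(grid: Grid) -> tuple[float, float]:
    """(metres per deg lon, metres per deg lat) at the grid's reference latitude."""
    m_lon = M_PER_DEG * np.cos(np.deg2rad(grid.mid_lat))
    return m_lon, M_PER_DEG


def make_flow(name: str, grid: Grid, **params: float) -> FlowFunc:
    """Build a velocity function for one of the named analytic flows.

    Parameters are flow specific: ``uniform(u, v)``; ``solid_rotation(omega,
    center_lat, center_lon)`` with omega in rad/s; ``double_gyre(amplitude,
    eps, omega)`` with amplitude in m^2/s (stream-function scale), omega in
    rad/s.  Unknown names raise :class:`ConfigError`.
    """
    for key, value in params.items():
        if not np.isfinite(value):
            raise ConfigError(f"flow parameter {key}={value!r} is not finite")

    m_lon, m_lat = projection_scales(grid)

    if name == "uniform":
        u0 = float(params.get("u", 0.0))
        v0 = float(params.get("v", 0.0))

        def flow(lon: np.ndarray, lat: np.ndarray, t: float):
            shape = np.broadcast(lon, lat).shape
            return np.full(shape, u0), np.full(shape, v0)

        return flow

    if name == "solid_rotation":
        omega = float(params.get("omega", 1e-6))
        clat = float(params.get("center_lat", grid.lat0 + grid.nlat / 2.0))
        clon = float(params.get("center_lon", grid.lon0 + grid.nlon / 2.0))

        def flow(lon: np.ndarray, lat: np.ndarray, t: float):
            x = (np.asarray(lon) - clon) * m_lon
            y = (np.asarray(lat) - clat) * m_lat
            return -omega * y, omega * x

        return flow

    if name == "double_gyre":
        amp = float(params.get("amplitude", 1e4))
        eps = float(params.get("eps", 0.0))
        omega = float(params.get("omega", 2 * np.pi / (30 * 86400.0)))
        lx = grid.nlon * m_lon  # domain size in metres
        ly = grid.nlat * m_lat

        def flow(lon: np.ndarray, lat: np.ndarray, t: float):
            # nondimensional coordinates: xt in [0, 2], yt in [0, 1]
            xt = 2.0 * (np.asarray(lon) - grid.lon0) / grid.nlon
            yt = (np.asarray(lat) - grid.lat0) / grid.nlat
            ts = t * 86400.0  # days -> seconds
            a = eps * np.sin(omega * ts)
            b = 1.0 - 2.0 * a
            f = a * xt**2 + b * xt
            dfdx = 2.0 * a * xt + b
            u = -(amp * np.pi / ly) * np.sin(np.pi * f) * np.cos(np.pi * yt)
            v = (2.0 * amp * np.pi / lx) * np.cos(np.pi * f) * np.sin(np.pi * yt) * dfdx
            return u, v

        return flow

    raise ConfigError(f"unknown flow {name!r}; expected one of {FLOW_NAMES}")


def gen_velocity_field(
    name: str,
    grid: Grid,
    times: Sequence[float],
    **params: float,
) -> xr.Dataset:
    """Sample an analytic flow onto the grid nodes at the given times.

    Returns an xarray Dataset with dimensions ``(time, lat, lon)`` and
    variables ``u``, ``v`` in m/s; time is in days.  This is the same layout
    the NetCDF reader ingests, so analytic and file-based fields are
    interchangeable downstream.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ConfigError("times must be a non-empty 1-D sequence of days")
    flow = make_flow(name, grid, **params)
    lats = np.arange(grid.lat0, grid.lat_max + 1, dtype=float)
    lons = np.arange(grid.lon0, grid.lon_max + 1, dtype=float)
    lon2, lat2 = np.meshgrid(lons, lats)
    u = np.empty((times.size, lats.size, lons.size))
    v = np.empty_like(u)
    for k, t in enumerate(times):
        uk, vk = flow(lon2, lat2, float(t))
        u[k], v[k] = uk, vk
    return xr.Dataset(
        {
            "u": (("time", "lat", "lon"), u, {"units": "m s-1"}),
            "v": (("time", "lat", "lon"), v, {"units": "m s-1"}),
        },
        coords={"time": ("time", times, {"units": "days"}), "lat": lats, "lon": lons},
    )


def write_velocity(ds: xr.Dataset, path: str) -> None:
    """Write a velocity field as classic NetCDF (scipy engine)."""
    ds.to_netcdf(path, engine="scipy")


def read_velocity(path: str) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy")
    missing = {"u", "v"} - set(ds.data_vars)
    if missing:
        raise ConfigError(f"velocity file {path} lacks variables {sorted(missing)}")
    return ds.load()
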