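"""Gridded wind fields: container, NetCDF round trip, interpolation.

A :class:`WindField` holds u/v wind components on a regular
(time, level, lat, lon) grid together with a land/sea mask and terrain
elevation on the (lat, lon) plane. Units are m/s for winds, metres for
levels and terrain, decimal degrees for the horizontal axes, and UTC
timestamps for the time axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

HOUR = np.timedelta64(3600, "s")


def _hours_since(times: np.ndarray, t0: np.datetime64) -> np.ndarray:
    return (times - t0) / HOUR


@dataclass
class WindField:
    """u/v winds on a (time, level, lat, lon) grid plus surface fields."""

    times: np.ndarray      # datetime64[s], strictly increasing
    levels: np.ndarray     # m a.s.l., strictly increasing
    lats: np.ndarray       # degrees, strictly increasing
    lons: np.ndarray       # degrees, strictly increasing
    u: np.ndarray          # (time, level, lat, lon) m/s
    v: np.ndarray          # same shape
    landmask: np.ndarray   # (lat, lon) bool, True = land
    terrain: np.ndarray    # (lat, lon) m

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.levels = np.asarray(self.levels, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        for name in ("times", "levels", "lats", "lons"):
            ax = getattr(self, name)
            vals = ax.astype("int64") if ax.dtype.kind == "M" else ax
            if ax.size > 1 and not np.all(np.diff(vals) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        shape = (self.times.size, self.levels.size, self.lats.size, self.lons.size)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(f"u/v must have shape {shape}")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("u/v must be finite")
        self.landmask = np.asarray(self.landmask, dtype=bool)
        self.terrain = np.asarray(self.terrain, dtype=float)
        if self.landmask.shape != shape[2:] or self.terrain.shape != shape[2:]:
            raise ValueError("landmask/terrain must have shape (lat, lon)")
        self._build_interpolators()

    def _build_interpolators(self) -> None:
        t0 = self.times[0]
        axes = [
            _hours_since(self.times, t0).astype(float),
            self.levels,
            self.lats,
            self.lons,
        ]
        # RegularGridInterpolator needs >= 2 points per axis; duplicate
        # singleton axes (the field is constant along them).
        arrs = {"u": self.u, "v": self.v}
        full_axes = []
        for ax in axes:
            if ax.size == 1:
                full_axes.append(np.array([ax[0], ax[0] + 1.0]))
            else:
                full_axes.append(ax)
        for name, arr in arrs.items():
            for d, ax in enumerate(axes):
                if ax.size == 1:
                    arr = np.concatenate([arr, arr], axis=d)
            arrs[name] = arr
        self._t0 = t0
        self._interp_u = RegularGridInterpolator(full_axes, arrs["u"], method="linear")
        self._interp_v = RegularGridInterpolator(full_axes, arrs["v"], method="linear")

    # -- queries ---------------------------------------------------------

    def in_horizontal_bounds(self, lon: float, lat: float) -> bool:
        return (
            self.lons[0] <= lon <= self.lons[-1]
            and self.lats[0] <= lat <= self.lats[-1]
        )

    def in_time_bounds(self, t: np.datetime64) -> bool:
        return self.times[0] <= t <= self.times[-1]

    def interpolate_wind(
        self, t: np.datetime64, lon: float, lat: float, alt: float
    ) -> tuple[float, float]:
        """Wind (u, v) in m/s at a point: linear in time and altitude,
        bilinear in lon/lat. Altitude outside the level span is clamped
        to the nearest level."""
        if not self.in_horizontal_bounds(lon, lat):
            raise OutsideGridError(f"({lon}, {lat}) outside horizontal grid")
        t = np.datetime64(t, "s")
        if not self.in_time_bounds(t):
            raise OutsideGridError(f"{t} outside time span of wind field")
        alt = float(np.clip(alt, self.levels[0], self.levels[-1]))
        th = float(_hours_since(np.asarray([t], dtype="datetime64[s]"), self._t0)[0])
        pt = np.array([[th, alt, lat, lon]])
        return float(self._interp_u(pt)[0]), float(self._interp_v(pt)[0])

    def is_land(self, lon: float, lat: float) -> bool:
        """Land/sea at the nearest grid cell centre."""
        if not self.in_horizontal_bounds(lon, lat):
            raise OutsideGridError(f"({lon}, {lat}) outside horizontal grid")
        i = int(np.argmin(np.abs(self.lats - lat)))
        j = int(np.argmin(np.abs(self.lons - lon)))
        return bool(self.landmask[i, j])

    def terrain_at(self, lon: float, lat: float) -> float:
        i = int(np.argmin(np.abs(self.lats - lat)))
        j = int(np.argmin(np.abs(self.lons - lon)))
        return float(self.terrain[i, j])

    # -- NetCDF round trip ----------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            data_vars={
                "u": (("time", "level", "lat", "lon"), self.u, {"units": "m s-1"}),
                "v": (("time", "level", "lat", "lon"), self.v, {"units": "m s-1"}),
                "landmask": (("lat", "lon"), self.landmask.astype(np.int8)),
                "terrain": (("lat", "lon"), self.terrain, {"units": "m"}),
            },
            coords={
                "time": self.times,
                "level": ("level", self.levels, {"units": "m"}),
                "lat": ("lat", self.lats, {"units": "degrees_north"}),
                "lon": ("lon", self.lons, {"units": "degrees_east"}),
            },
        )

    def to_netcdf(self, path) -> None:
        # netCDF3 classic via the scipy engine: portable, no extra deps
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "WindField":
        return cls(
            times=ds["time"].values,
            levels=ds["level"].values,
            lats=ds["lat"].values,
            lons=ds["lon"].values,
            u=ds["u"].values,
            v=ds["v"].values,
            landmask=ds["landmask"].values.astype(bool),
            terrain=ds["terrain"].values,
        )

    @classmethod
    def from_netcdf(cls, path) -> "WindField":
        with xr.open_dataset(path) as ds:
            return cls.from_dataset(ds.load())


class OutsideGridError(Exception):
    """Query point lies outside the wind-field grid."""
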