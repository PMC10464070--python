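"""Gridded weather fields, space-time interpolation, and wind decomposition.

The analyses annotate every GPS fix with reanalysis-style weather: fields on
a regular (time, lat, lon) grid at 0.25 deg / 1 h for the atmospheric
variables and 0.75 deg / 6 h for the three cloud layers.  Values are
interpolated bilinearly in space at the two bracketing time slices and then
linearly in time — exact on fields linear in lat, lon and t, and always
within the envelope of the eight bracketing nodes.

Wind is stored as eastward (u) and northward (v) components in m/s.
Direction is the bearing the wind blows TOWARD.  The support components
along a flight direction are

    tailwind  = 3.6 * v_wind * cos(delta)      (signed; >0 aids flight)
    crosswind = |3.6 * v_wind * sin(delta)|    (magnitude only)

with delta the circular difference between flight direction and wind
direction, reported in km/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import xarray as xr

WEATHER_VARIABLES = (
    "temperature",
    "precipitation",
    "rel_humidity",
    "pressure",
    "wind_u",
    "wind_v",
    "cloud_low",
    "cloud_medium",
    "cloud_high",
)
CLOUD_VARIABLES = ("cloud_low", "cloud_medium", "cloud_high")

MS_TO_KMH = 3.6


class ExtrapolationError(ValueError):
    """Query outside the spatial/temporal hull of a grid."""


class GridInvariantError(ValueError):
    """Grid arrays violate the container invariants."""


@dataclass
class WeatherGrid:
    """One variable on a dense regular (time, lat, lon) grid."""

    variable: str
    times: np.ndarray  # datetime64[ns], strictly increasing
    lats: np.ndarray  # degrees, strictly increasing
    lons: np.ndarray  # degrees, strictly increasing
    values: np.ndarray  # [time, lat, lon]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.variable not in WEATHER_VARIABLES:
            raise GridInvariantError(f"unknown variable {self.variable!r}")
        for name, arr in (("times", self.times), ("lats", self.lats), ("lons", self.lons)):
            diffs = np.diff(arr.astype("int64") if arr.dtype.kind == "M" else arr)
            if arr.ndim != 1 or len(arr) < 2 or not np.all(diffs > 0):
                raise GridInvariantError(f"{name} must be a strictly increasing vector of length >= 2")
        if self.values.shape != (len(self.times), len(self.lats), len(self.lons)):
            raise GridInvariantError("values shape mismatch with coordinate vectors")
        if not np.all(np.isfinite(self.values)):
            raise GridInvariantError("non-finite values in grid")

    @property
    def spatial_res_deg(self) -> float:
        return float(np.round(np.mean(np.diff(self.lats)), 6))

    @property
    def temporal_step_h(self) -> float:
        return float(np.mean(np.diff(self.times)) / np.timedelta64(3600, "s"))

    def to_dataarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values,
            coords={"time": self.times, "lat": self.lats, "lon": self.lons},
            dims=("time", "lat", "lon"),
            name=self.variable,
        )

    @classmethod
    def from_dataarray(cls, da: xr.DataArray, variable: str | None = None) -> "WeatherGrid":
        return cls(
            variable=variable or str(da.name),
            times=da["time"].values,
            lats=da["lat"].values,
            lons=da["lon"].values,
            values=da.values,
        )


def _times_to_seconds(times: np.ndarray) -> np.ndarray:
    return times.astype("datetime64[ns]").astype("int64") / 1e9


def interpolate_at(grid: WeatherGrid, lats, lons, times) -> np.ndarray:
    """Bilinear-in-space, linear-in-time interpolation at query points.

    Accepts scalars or equal-length arrays; raises ExtrapolationError for
    queries outside the grid hull (no clamping).  Returns an array (scalar
    queries give a 0-d-compatible length-1 result collapsed to float).
    """
    scalar = np.isscalar(lats) and np.isscalar(lons) and not isinstance(times, (np.ndarray, list, tuple, pd.Series, pd.DatetimeIndex))
    qla = np.atleast_1d(np.asarray(lats, dtype=float))
    qlo = np.atleast_1d(np.asarray(lons, dtype=float))
    qt = np.atleast_1d(np.asarray(times, dtype="datetime64[ns]"))
    qts = _times_to_seconds(qt)
    gts = _times_to_seconds(grid.times)

    if (
        qla.min() < grid.lats[0] or qla.max() > grid.lats[-1]
        or qlo.min() < grid.lons[0] or qlo.max() > grid.lons[-1]
        or qts.min() < gts[0] or qts.max() > gts[-1]
    ):
        raise ExtrapolationError(
            f"query outside hull of {grid.variable} grid "
            f"(lat [{grid.lats[0]}, {grid.lats[-1]}], lon [{grid.lons[0]}, {grid.lons[-1]}])"
        )

    def _brackets(coords, q):
        hi = np.searchsorted(coords, q, side="right")
        hi = np.clip(hi, 1, len(coords) - 1)
        lo = hi - 1
        w = (q - coords[lo]) / (coords[hi] - coords[lo])
        return lo, hi, w

    ia0, ia1, wa = _brackets(grid.lats, qla)
    io0, io1, wo = _brackets(grid.lons, qlo)
    it0, it1, wt = _brackets(gts, qts)

    V = grid.values
    out = np.zeros(len(qla), dtype=float)
    for (ti, tw) in ((it0, 1.0 - wt), (it1, wt)):
        plane = (
            V[ti, ia0, io0] * (1 - wa) * (1 - wo)
            + V[ti, ia1, io0] * wa * (1 - wo)
            + V[ti, ia0, io1] * (1 - wa) * wo
            + V[ti, ia1, io1] * wa * wo
        )
        out += tw * plane
    return float(out[0]) if scalar else out


def wind_speed_dir(u, v):
    """Speed (m/s) and blowing-toward bearing (deg in [0,360)) from u/v.

    For calm air (u = v = 0) speed is 0 and the direction is NaN (undefined).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite wind components")
    speed = np.hypot(u, v)
    direction = np.degrees(np.arctan2(u, v)) % 360.0
    direction = np.where(speed == 0.0, np.nan, direction)
    if u.ndim == 0:
        return float(speed), float(direction)
    return speed, direction


def dir_from_to_toward(dir_from_deg):
    """Convert a wind-origin bearing to the blowing-toward convention."""
    return (np.asarray(dir_from_deg, dtype=float) + 180.0) % 360.0


def _delta_rad(flight_dir_deg, wind_dir_to_deg):
    return np.radians(
        np.asarray(flight_dir_deg, dtype=float) - np.asarray(wind_dir_to_deg, dtype=float)
    )


def tailwind_kmh(wind_speed_ms, wind_dir_to_deg, flight_dir_deg):
    """Signed along-track wind support in km/h: 3.6 * v * cos(delta).

    Positive = tailwind, negative = headwind.
    """
    v = np.asarray(wind_speed_ms, dtype=float)
    if np.any(v < 0):
        raise ValueError("wind speed must be non-negative")
    out = MS_TO_KMH * v * np.cos(_delta_rad(flight_dir_deg, wind_dir_to_deg))
    return float(out) if out.ndim == 0 else out


def crosswind_kmh(wind_speed_ms, wind_dir_to_deg, flight_dir_deg):
    """Unsigned perpendicular wind component in km/h: |3.6 * v * sin(delta)|."""
    v = np.asarray(wind_speed_ms, dtype=float)
    if np.any(v < 0):
        raise ValueError("wind speed must be non-negative")
    out = np.abs(MS_TO_KMH * v * np.sin(_delta_rad(flight_dir_deg, wind_dir_to_deg)))
    return float(out) if out.ndim == 0 else out


@dataclass
class WeatherAtFix:
    """All annotated variables at one fix, plus derived wind speed/direction."""

    temperature: float
    precipitation: float
    rel_humidity: float
    pressure: float
    wind_u: float
    wind_v: float
    cloud_low: float
    cloud_medium: float
    cloud_high: float
    wind_speed_ms: float = field(init=False)
    wind_dir_to_deg: float = field(init=False)

    def __post_init__(self):
        self.wind_speed_ms, self.wind_dir_to_deg = wind_speed_dir(self.wind_u, self.wind_v)


def annotate_points(
    grids: Mapping[str, WeatherGrid], lats, lons, times
) -> pd.DataFrame:
    """Interpolate every supplied variable at each (lat, lon, time) query.

    Returns a DataFrame with one column per variable plus wind_speed_ms and
    wind_dir_to_deg when both wind components are present.
    """
    out = {}
    for name, grid in grids.items():
        out[name] = np.atleast_1d(interpolate_at(grid, lats, lons, times))
    df = pd.DataFrame(out)
    if "wind_u" in df and "wind_v" in df:
        speed, direction = wind_speed_dir(df["wind_u"].values, df["wind_v"].values)
        df["wind_speed_ms"] = speed
        df["wind_dir_to_deg"] = direction
    return df


# ---------------------------------------------------------------------------
# I/O: CF-style NetCDF and a long-format CSV dialect
# ---------------------------------------------------------------------------

def grids_to_dataset(grids: Mapping[str, WeatherGrid]) -> xr.Dataset:
    """Bundle same-resolution grids into one CF-style Dataset."""
    return xr.Dataset({name: g.to_dataarray() for name, g in grids.items()})


def write_netcdf(grids: Mapping[str, WeatherGrid], path) -> None:
    """Write grids sharing one coordinate system to NetCDF3 (scipy backend)."""
    ds = grids_to_dataset(grids)
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path) -> dict[str, WeatherGrid]:
    with xr.open_dataset(path, engine="scipy") as ds:
        return {
            str(name): WeatherGrid.from_dataarray(ds[name].load(), str(name))
            for name in ds.data_vars
        }


def write_csv(grids: Mapping[str, WeatherGrid], path) -> None:
    """Long-format CSV: variable,time_iso8601,lat,lon,value (desk-scale fixtures)."""
    frames = []
    for name, g in grids.items():
        t_idx, la_idx, lo_idx = np.meshgrid(
            np.arange(len(g.times)), np.arange(len(g.lats)), np.arange(len(g.lons)),
            indexing="ij",
        )
        frames.append(
            pd.DataFrame(
                {
                    "variable": name,
                    "time_iso8601": pd.DatetimeIndex(g.times[t_idx.ravel()]).strftime(
                        "%Y-%m-%dT%H:%M:%S"
                    ),
                    "lat": g.lats[la_idx.ravel()],
                    "lon": g.lons[lo_idx.ravel()],
                    "value": g.values.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_csv(path) -> dict[str, WeatherGrid]:
    df = pd.read_csv(path, parse_dates=["time_iso8601"])
    grids = {}
    for name, sub in df.groupby("variable", sort=False):
        times = np.sort(sub["time_iso8601"].unique())
        lats = np.sort(sub["lat"].unique())
        lons = np.sort(sub["lon"].unique())
        piv = sub.set_index(["time_iso8601", "lat", "lon"])["value"]
        values = piv.sort_index().to_numpy().reshape(len(times), len(lats), len(lons))
        grids[str(name)] = WeatherGrid(str(name), times, lats, lons, values)
    return grids
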