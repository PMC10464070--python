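"""Geodesic distance/bearing helpers and solar timing.

Distances are great-circle (haversine) on a sphere of mean radius
6371.0088 km; at the scales of a Mediterranean migration track (< 1000 km)
this is within 0.5% of a full ellipsoidal geodesic.  Sunrise/sunset follow
the standard NOAA solar-position equations with the conventional zenith of
90.833 deg (atmospheric refraction plus the solar radius).

"Hours after sunset" is the covariate used by the nocturnal-departure
analyses: 0 at local sunset, positive afterwards, with fixes between
midnight and local noon referenced to the *previous* evening's sunset so
the quantity is continuous across midnight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from enum import Enum
from typing import Optional

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: solar zenith angle at sunrise/sunset (refraction + solar radius), degrees
SUNSET_ZENITH_DEG = 90.833


class InvalidInputError(ValueError):
    """Raised for non-finite/out-of-range geographic or temporal inputs."""


class UndefinedBearingError(ValueError):
    """Raised when a bearing is requested between two identical points."""


class NotComputableError(ValueError):
    """Raised when a solar quantity does not exist (polar day/night)."""


class PolarFlag(str, Enum):
    NORMAL = "normal"
    POLAR_DAY = "polar_day"
    POLAR_NIGHT = "polar_night"


def _normalize_lon(lon: float) -> float:
    """Wrap a longitude into [-180, 180)."""
    return (lon + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class GeoPoint:
    """A position in decimal degrees; longitude normalized into [-180, 180)."""

    lat_deg: float
    lon_deg: float

    def __post_init__(self):
        if not (math.isfinite(self.lat_deg) and math.isfinite(self.lon_deg)):
            raise InvalidInputError("coordinates must be finite")
        if not -90.0 <= self.lat_deg <= 90.0:
            raise InvalidInputError(f"latitude {self.lat_deg} outside [-90, 90]")
        object.__setattr__(self, "lon_deg", _normalize_lon(self.lon_deg))


@dataclass(frozen=True)
class SolarEvents:
    date: date
    sunrise_utc: Optional[datetime]
    sunset_utc: Optional[datetime]
    polar_flag: PolarFlag = PolarFlag.NORMAL


def great_circle_km(a: GeoPoint, b: GeoPoint) -> float:
    """Haversine great-circle distance in km between two points."""
    la1, lo1, la2, lo2 = map(
        math.radians, (a.lat_deg, a.lon_deg, b.lat_deg, b.lon_deg)
    )
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def great_circle_km_vec(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Vectorized haversine (decimal-degree arrays) in km."""
    la1, lo1, la2, lo2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    h = (
        np.sin((la2 - la1) / 2.0) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def initial_bearing_deg(a: GeoPoint, b: GeoPoint) -> float:
    """Initial great-circle bearing from a to b, degrees clockwise from north in [0, 360)."""
    if abs(a.lat_deg - b.lat_deg) < 1e-9 and abs(a.lon_deg - b.lon_deg) < 1e-9:
        raise UndefinedBearingError("bearing undefined for coincident points")
    la1, la2 = math.radians(a.lat_deg), math.radians(b.lat_deg)
    dlon = math.radians(b.lon_deg - a.lon_deg)
    y = math.sin(dlon) * math.cos(la2)
    x = math.cos(la1) * math.sin(la2) - math.sin(la1) * math.cos(la2) * math.cos(dlon)
    return math.degrees(math.atan2(y, x)) % 360.0


def initial_bearing_deg_vec(lat1, lon1, lat2, lon2) -> np.ndarray:
    la1, la2 = np.radians(np.asarray(lat1, float)), np.radians(np.asarray(lat2, float))
    dlon = np.radians(np.asarray(lon2, float) - np.asarray(lon1, float))
    y = np.sin(dlon) * np.cos(la2)
    x = np.cos(la1) * np.sin(la2) - np.sin(la1) * np.cos(la2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination_point(p: GeoPoint, bearing_deg: float, distance_km: float) -> GeoPoint:
    """Point reached travelling distance_km along the initial bearing from p."""
    delta = distance_km / EARTH_RADIUS_KM
    theta = math.radians(bearing_deg)
    la1 = math.radians(p.lat_deg)
    lo1 = math.radians(p.lon_deg)
    la2 = math.asin(
        math.sin(la1) * math.cos(delta) + math.cos(la1) * math.sin(delta) * math.cos(theta)
    )
    lo2 = lo1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(la1),
        math.cos(delta) - math.sin(la1) * math.sin(la2),
    )
    return GeoPoint(math.degrees(la2), _normalize_lon(math.degrees(lo2)))


# ---------------------------------------------------------------------------
# NOAA solar-position equations
# ---------------------------------------------------------------------------

def _julian_day(d: date) -> float:
    """Julian day number at 0h UT for a calendar date."""
    y, m, dd = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + dd + b - 1524.5


def _solar_params(jc: float):
    """Equation of time (minutes) and solar declination (deg) at Julian century jc."""
    gml = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    ctr = (
        math.sin(math.radians(gma)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(math.radians(2 * gma)) * (0.019993 - 0.000101 * jc)
        + math.sin(math.radians(3 * gma)) * 0.000289
    )
    true_long = gml + ctr
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    decl = math.degrees(
        math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    )
    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2.0 * math.radians(gml))
        - 2.0 * ecc * math.sin(math.radians(gma))
        + 4.0 * ecc * var_y * math.sin(math.radians(gma)) * math.cos(2.0 * math.radians(gml))
        - 0.5 * var_y * var_y * math.sin(4.0 * math.radians(gml))
        - 1.25 * ecc * ecc * math.sin(2.0 * math.radians(gma))
    )
    return eq_time, decl


def solar_events(p: GeoPoint, d: date, utc_offset_minutes: int = 0) -> SolarEvents:
    """NOAA-style sunrise/sunset for a date at a location.

    Polar day/night is flagged (sunrise/sunset absent), never raised.
    The returned timestamps are timezone-aware UTC datetimes; utc_offset_minutes
    only selects which *civil* day the events are computed for.
    """
    if abs(utc_offset_minutes) > 14 * 60:
        raise InvalidInputError("utc offset outside +/-14 h")
    if not 1990 <= d.year <= 2050:
        raise InvalidInputError("date outside supported era 1990-2050")
    # solar noon near local civil noon of the requested day
    jd = _julian_day(d) + 0.5 - utc_offset_minutes / 1440.0
    jc = (jd - 2451545.0) / 36525.0
    eq_time, decl = _solar_params(jc)
    lat_r = math.radians(p.lat_deg)
    dec_r = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(SUNSET_ZENITH_DEG)) / (math.cos(lat_r) * math.cos(dec_r))
        - math.tan(lat_r) * math.tan(dec_r)
    )
    if cos_ha < -1.0:
        return SolarEvents(d, None, None, PolarFlag.POLAR_DAY)
    if cos_ha > 1.0:
        return SolarEvents(d, None, None, PolarFlag.POLAR_NIGHT)
    ha_deg = math.degrees(math.acos(cos_ha))
    # solar noon in minutes past UTC midnight of calendar day d
    solar_noon_min = 720.0 - 4.0 * p.lon_deg - eq_time
    midnight_utc = datetime(d.year, d.month, d.day, tzinfo=timezone.utc)
    sunrise = midnight_utc + timedelta(minutes=solar_noon_min - ha_deg * 4.0)
    sunset = midnight_utc + timedelta(minutes=solar_noon_min + ha_deg * 4.0)
    return SolarEvents(d, sunrise, sunset, PolarFlag.NORMAL)


def _as_utc(t: datetime) -> datetime:
    if t.tzinfo is None:
        return t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc)


def hours_after_sunset(t: datetime, p: GeoPoint, utc_offset_minutes: int = 0) -> float:
    """Signed hours since the reference sunset for timestamp t at p.

    0 at sunset, positive after.  Fixes whose local civil time falls before
    noon are referenced to the previous evening's sunset, which makes the
    quantity continuous across midnight for nocturnal observations.
    """
    t_utc = _as_utc(t)
    local = t_utc + timedelta(minutes=utc_offset_minutes)
    ref_date = local.date()
    if local.hour < 12:
        ref_date = ref_date - timedelta(days=1)
    ev = solar_events(p, ref_date, utc_offset_minutes)
    if ev.polar_flag is not PolarFlag.NORMAL:
        raise NotComputableError(f"no sunset on {ref_date} at {p}: {ev.polar_flag.value}")
    return (t_utc - ev.sunset_utc).total_seconds() / 3600.0


def _last_sunday(year: int, month: int) -> date:
    d = date(year, month, 31)
    return d - timedelta(days=(d.weekday() + 1) % 7)


def italian_utc_offset_minutes(d: date) -> int:
    """Civil Italian offset: UTC+2 (CEST) from the last Sunday of March to the
    last Sunday of October, UTC+1 (CET) otherwise."""
    return 120 if _last_sunday(d.year, 3) <= d < _last_sunday(d.year, 10) else 60


def day_of_year(d: date) -> int:
    """Calendar day of year (1 = 1 January)."""
    return d.timetuple().tm_yday
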