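"""Independent sunset oracle: the classic Julian-date sunset equation with
solar-transit iteration (a different formulation from the package's
NOAA-spreadsheet equations), accurate to about a minute."""

import math
from datetime import date, datetime, timedelta, timezone


def sunset_utc(lat_deg: float, lon_deg: float, d: date) -> datetime:
    # days since J2000.0, corrected for leap seconds/terrestrial time offset
    jd = _julian_day(d)
    n = jd - 2451545.0 + 0.0008
    j_star = n - lon_deg / 360.0  # mean solar time
    M = (357.5291 + 0.98560028 * j_star) % 360.0  # solar mean anomaly
    C = (
        1.9148 * math.sin(math.radians(M))
        + 0.02 * math.sin(math.radians(2 * M))
        + 0.0003 * math.sin(math.radians(3 * M))
    )
    lam = (M + C + 180.0 + 102.9372) % 360.0  # ecliptic longitude
    j_transit = (
        2451545.0 + j_star + 0.0053 * math.sin(math.radians(M))
        - 0.0069 * math.sin(math.radians(2 * lam))
    )
    decl = math.degrees(math.asin(math.sin(math.radians(lam)) * math.sin(math.radians(23.4397))))
    cos_ha = (
        math.sin(math.radians(-0.833)) - math.sin(math.radians(lat_deg)) * math.sin(math.radians(decl))
    ) / (math.cos(math.radians(lat_deg)) * math.cos(math.radians(decl)))
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError("polar day/night")
    ha = math.degrees(math.acos(cos_ha))
    j_set = j_transit + ha / 360.0
    return _jd_to_datetime(j_set)


def _julian_day(d: date) -> float:
    y, m, dd = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + dd + b - 1524.5 + 0.5


def _jd_to_datetime(jd: float) -> datetime:
    # JD 2440587.5 = 1970-01-01T00:00Z
    secs = (jd - 2440587.5) * 86400.0
    return datetime(1970, 1, 1, tzinfo=timezone.utc) + timedelta(seconds=secs)
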