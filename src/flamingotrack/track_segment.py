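"""Segmentation of raw GPS fix streams into migration events.

A juvenile is a *migrant* when it leaves on a flight beyond a 100-km radius
of the natal colony and reaches its non-breeding site before 1 November of
the hatching year; otherwise it is a *resident*.  An event consists of the
departure fix (first in-flight location after leaving the colony), in-flight
fixes, optional stopovers (dwells of >= 12 h), and the arrival fix — entry
into the site held for >= 20 days (the non-breeding site) after a directed
movement of > 100 km/day.

The raw data never label behaviour, so "in flight" is operationalised:
segment speed to the next fix >= `flight_speed_kmh` (default 20 km/h,
well below flamingo cruising speed but above foraging moves) while moving
away from the colony.  The colony residence radius (5 km) and the dwell
radius (15 km around the running dwell centroid) are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .geo_solar import (
    GeoPoint,
    InvalidInputError,
    great_circle_km,
    great_circle_km_vec,
    initial_bearing_deg,
    italian_utc_offset_minutes,
)

MIGRATION_RADIUS_KM = 100.0
DEFAULT_FLIGHT_SPEED_KMH = 20.0
DEFAULT_COLONY_RADIUS_KM = 5.0
DEFAULT_DWELL_RADIUS_KM = 15.0
STOPOVER_MIN_H = 12.0
NONBREEDING_MIN_DAYS = 20.0
DIRECTED_KM_PER_DAY = 100.0


class NoDepartureError(ValueError):
    """No excursion beyond the migration radius was found."""


class OpenEndedEventError(ValueError):
    """Track ends before any dwell satisfies the stopover/arrival rules."""


class DataQualityWarning(UserWarning):
    pass


@dataclass(frozen=True)
class Fix:
    bird_id: str
    t_utc: datetime
    pos: GeoPoint


@dataclass
class Track:
    bird_id: str
    colony_id: str
    hatch_year: int
    fixes: list  # of Fix, strictly increasing times

    def __post_init__(self):
        if len(self.fixes) < 2:
            raise InvalidInputError("a track needs at least two fixes")
        ts = [f.t_utc for f in self.fixes]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise InvalidInputError("fix timestamps must be strictly increasing")

    def lats(self) -> np.ndarray:
        return np.array([f.pos.lat_deg for f in self.fixes])

    def lons(self) -> np.ndarray:
        return np.array([f.pos.lon_deg for f in self.fixes])

    def times(self) -> np.ndarray:
        return np.array([np.datetime64(f.t_utc.replace(tzinfo=None), "ns") for f in self.fixes])


@dataclass
class Stopover:
    entry: Fix
    exit: Fix
    dwell_h: float


@dataclass
class SegmentKinematics:
    from_fix: Fix
    to_fix: Fix
    dt_h: float
    dist_km: float
    speed_kmh: float
    bearing_deg: float
    cumulative_km: float  # distance travelled up to from_fix


@dataclass
class MigrationEvent:
    bird_id: str
    departure_fix: Fix
    arrival_fix: Fix
    in_flight: list
    stopovers: list
    total_distance_km: float
    duration_h: float
    mean_speed_kmh: float
    max_speed_kmh: float
    destination_bearing_deg: float


def _displacements_km(track: Track, colony: GeoPoint) -> np.ndarray:
    return great_circle_km_vec(
        track.lats(), track.lons(), colony.lat_deg, colony.lon_deg
    )


def _inflight_flags(track: Track, colony: GeoPoint, flight_speed_kmh: float) -> np.ndarray:
    """fix i is in-flight when speed to fix i+1 >= threshold and the
    displacement from the colony increases from i to i+1.  The last fix
    inherits the previous flag."""
    lats, lons = track.lats(), track.lons()
    t = np.array([f.t_utc.timestamp() for f in track.fixes])
    d = great_circle_km_vec(lats[:-1], lons[:-1], lats[1:], lons[1:])
    dt_h = np.diff(t) / 3600.0
    speed = d / dt_h
    disp = _displacements_km(track, colony)
    flags = (speed >= flight_speed_kmh) & (np.diff(disp) > 0)
    return np.append(flags, flags[-1] if len(flags) else False)


def detect_departure(
    track: Track,
    colony: GeoPoint,
    flight_speed_kmh: float = DEFAULT_FLIGHT_SPEED_KMH,
    colony_radius_km: float = DEFAULT_COLONY_RADIUS_KM,
) -> Fix:
    """First in-flight fix after last leaving the colony on the excursion
    that crosses the 100-km radius."""
    disp = _displacements_km(track, colony)
    beyond = np.nonzero(disp > MIGRATION_RADIUS_KM)[0]
    if len(beyond) == 0:
        raise NoDepartureError(f"{track.bird_id}: no fix beyond {MIGRATION_RADIUS_KM} km")
    cross = beyond[0]
    inside = np.nonzero(disp[:cross] <= colony_radius_km)[0]
    if len(inside) == 0:
        warnings.warn(
            f"{track.bird_id}: track already away from colony at first fix",
            DataQualityWarning,
        )
        return track.fixes[0]
    last_at_colony = inside[-1]
    flags = _inflight_flags(track, colony, flight_speed_kmh)
    for i in range(last_at_colony + 1, cross + 1):
        if flags[i]:
            return track.fixes[i]
    # crossing without a flagged flight fix (large gaps): use the crossing fix
    warnings.warn(
        f"{track.bird_id}: no in-flight fix flagged before the 100-km crossing",
        DataQualityWarning,
    )
    return track.fixes[cross]


def _dwells(track: Track, start_idx: int, dwell_radius_km: float):
    """Greedy dwell clustering from start_idx: consecutive fixes within
    dwell_radius_km of the running centroid.  Yields (i0, i1) index spans
    with dwell duration >= STOPOVER_MIN_H."""
    fixes = track.fixes
    n = len(fixes)
    i = start_idx
    while i < n:
        lat_c, lon_c = fixes[i].pos.lat_deg, fixes[i].pos.lon_deg
        j = i + 1
        count = 1
        while j < n:
            p = fixes[j].pos
            if great_circle_km(GeoPoint(lat_c, lon_c), p) > dwell_radius_km:
                break
            count += 1
            lat_c += (p.lat_deg - lat_c) / count
            lon_c += (p.lon_deg - lon_c) / count
            j += 1
        dwell_h = (fixes[j - 1].t_utc - fixes[i].t_utc).total_seconds() / 3600.0
        if dwell_h >= STOPOVER_MIN_H:
            yield i, j - 1
            i = j
        else:
            i += 1


def _directed_approach(track: Track, entry_idx: int) -> bool:
    """Directed movement of > 100 km/day into the dwell: the maximum
    displacement between any two fixes at most 24 h apart, taken over the
    window from 24 h before the dwell entry to 12 h after it (the flight
    ends at the arrival site, which may already lie inside the dwell)."""
    entry = track.fixes[entry_idx]
    t0 = entry.t_utc - timedelta(hours=24)
    t1 = entry.t_utc + timedelta(hours=12)
    window = [f for f in track.fixes if t0 <= f.t_utc <= t1]
    for i, a in enumerate(window):
        for b in window[i + 1 :]:
            if (b.t_utc - a.t_utc) <= timedelta(hours=24) and great_circle_km(
                a.pos, b.pos
            ) > DIRECTED_KM_PER_DAY:
                return True
    return False


def _check_dwell_gaps(track: Track, i0: int, i1: int) -> None:
    ts = [track.fixes[k].t_utc for k in range(i0, i1 + 1)]
    gaps = [(b - a).total_seconds() / 3600.0 for a, b in zip(ts, ts[1:])]
    if gaps and max(gaps) > 12.0:
        warnings.warn(
            f"{track.bird_id}: gap > 12 h inside a candidate dwell voids its "
            "duration certificate",
            DataQualityWarning,
        )


def detect_arrival_and_stopovers(
    track: Track,
    departure: Fix,
    dwell_radius_km: float = DEFAULT_DWELL_RADIUS_KM,
):
    """Arrival fix (entry into the >= 20-day site) and intermediate stopovers."""
    dep_idx = next(
        i for i, f in enumerate(track.fixes) if f.t_utc == departure.t_utc
    )
    stopovers: list[Stopover] = []
    end_t = track.fixes[-1].t_utc
    for i0, i1 in _dwells(track, dep_idx + 1, dwell_radius_km):
        _check_dwell_gaps(track, i0, i1)
        dwell_h = (track.fixes[i1].t_utc - track.fixes[i0].t_utc).total_seconds() / 3600.0
        if dwell_h >= NONBREEDING_MIN_DAYS * 24.0 and _directed_approach(track, i0):
            return track.fixes[i0], stopovers
        if dwell_h >= STOPOVER_MIN_H:
            stopovers.append(Stopover(track.fixes[i0], track.fixes[i1], dwell_h))
    raise OpenEndedEventError(
        f"{track.bird_id}: no >= {NONBREEDING_MIN_DAYS}-day dwell before data end "
        f"({end_t.isoformat()})"
    )


def classify_strategy(
    track: Track,
    colony: GeoPoint,
    deadline: date | None = None,
    **kwargs,
) -> str:
    """'migrant' iff the track crosses the 100-km radius AND the event's
    arrival precedes 1 November (local civil time) of the hatching year."""
    if deadline is None:
        deadline = date(track.hatch_year, 11, 1)
    try:
        dep = detect_departure(track, colony, **kwargs)
        arrival, _ = detect_arrival_and_stopovers(track, dep)
    except (NoDepartureError, OpenEndedEventError):
        return "resident"
    offset = italian_utc_offset_minutes(arrival.t_utc.date())
    local_arrival = (arrival.t_utc + timedelta(minutes=offset)).date()
    return "migrant" if local_arrival < deadline else "resident"


def segment_kinematics(fixes: Sequence[Fix], exclude_final: bool = False):
    """Per consecutive pair: dt, distance, speed, bearing and the cumulative
    distance travelled up to the segment's starting fix."""
    if len(fixes) < 2:
        raise InvalidInputError("need at least two fixes")
    segs: list[SegmentKinematics] = []
    cum = 0.0
    for a, b in zip(fixes, fixes[1:]):
        dt_h = (b.t_utc - a.t_utc).total_seconds() / 3600.0
        if dt_h <= 0:
            raise InvalidInputError("non-increasing fix times")
        dist = great_circle_km(a.pos, b.pos)
        bearing = initial_bearing_deg(a.pos, b.pos) if dist > 1e-9 else np.nan
        segs.append(SegmentKinematics(a, b, dt_h, dist, dist / dt_h, bearing, cum))
        cum += dist
    if exclude_final:
        segs = segs[:-1]
    return segs


def extract_event(
    track: Track,
    colony: GeoPoint,
    flight_speed_kmh: float = DEFAULT_FLIGHT_SPEED_KMH,
    colony_radius_km: float = DEFAULT_COLONY_RADIUS_KM,
    dwell_radius_km: float = DEFAULT_DWELL_RADIUS_KM,
) -> MigrationEvent:
    """Full migration event for a migrant track."""
    dep = detect_departure(track, colony, flight_speed_kmh, colony_radius_km)
    arrival, stopovers = detect_arrival_and_stopovers(track, dep, dwell_radius_km)
    i_dep = next(i for i, f in enumerate(track.fixes) if f.t_utc == dep.t_utc)
    i_arr = next(i for i, f in enumerate(track.fixes) if f.t_utc == arrival.t_utc)
    journey = track.fixes[i_dep : i_arr + 1]
    segs = segment_kinematics(journey)
    total = sum(s.dist_km for s in segs)
    duration_h = (arrival.t_utc - dep.t_utc).total_seconds() / 3600.0
    speeds = [s.speed_kmh for s in segs]
    return MigrationEvent(
        bird_id=track.bird_id,
        departure_fix=dep,
        arrival_fix=arrival,
        in_flight=journey[1:-1],
        stopovers=stopovers,
        total_distance_km=total,
        duration_h=duration_h,
        mean_speed_kmh=total / duration_h if duration_h > 0 else np.nan,
        max_speed_kmh=max(speeds) if speeds else np.nan,
        destination_bearing_deg=initial_bearing_deg(dep.pos, arrival.pos),
    )


def summarize_event(event: MigrationEvent) -> dict:
    """One tidy summary row per event (departure date, destination, duration,
    distance, mean/max speed)."""
    return {
        "bird_id": event.bird_id,
        "departure_utc": event.departure_fix.t_utc.isoformat(),
        "arrival_utc": event.arrival_fix.t_utc.isoformat(),
        "arrival_lat": event.arrival_fix.pos.lat_deg,
        "arrival_lon": event.arrival_fix.pos.lon_deg,
        "duration_h": event.duration_h,
        "total_distance_km": event.total_distance_km,
        "mean_speed_kmh": event.mean_speed_kmh,
        "max_speed_kmh": event.max_speed_kmh,
        "destination_bearing_deg": event.destination_bearing_deg,
        "n_stopovers": len(event.stopovers),
    }


# ---------------------------------------------------------------------------
# Movebank-style I/O
# ---------------------------------------------------------------------------

MOVEBANK_COLUMNS = {
    "individual-local-identifier": "bird_id",
    "timestamp": "t_utc",
    "location-lat": "lat",
    "location-long": "lon",
}


def read_movebank_csv(path, colony_ids: Optional[dict] = None, hatch_years: Optional[dict] = None):
    """Load tracks from a Movebank-style CSV.

    colony_ids / hatch_years map bird_id to metadata; unknown birds get
    colony_id '' and the hatch year of their first fix.
    """
    df = pd.read_csv(path)
    df = df.rename(columns=MOVEBANK_COLUMNS)
    df["t_utc"] = pd.to_datetime(df["t_utc"], utc=True)
    tracks = []
    for bird_id, sub in df.groupby("bird_id", sort=True):
        sub = sub.sort_values("t_utc")
        fixes = [
            Fix(str(bird_id), t.to_pydatetime(), GeoPoint(la, lo))
            for t, la, lo in zip(sub["t_utc"], sub["lat"], sub["lon"])
        ]
        tracks.append(
            Track(
                bird_id=str(bird_id),
                colony_id=(colony_ids or {}).get(str(bird_id), ""),
                hatch_year=(hatch_years or {}).get(str(bird_id), fixes[0].t_utc.year),
                fixes=fixes,
            )
        )
    return tracks


def write_movebank_csv(tracks: Iterable[Track], path) -> None:
    rows = []
    for tr in tracks:
        for f in tr.fixes:
            rows.append(
                {
                    "individual-local-identifier": tr.bird_id,
                    "timestamp": f.t_utc.astimezone(timezone.utc).strftime("%Y-%m-%d %H:%M:%S"),
                    "location-lat": f.pos.lat_deg,
                    "location-long": f.pos.lon_deg,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def events_to_frame(events: Iterable[MigrationEvent]) -> pd.DataFrame:
    return pd.DataFrame([summarize_event(e) for e in events])
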