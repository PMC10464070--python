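"""Track segmentation tests on hand-built fix streams with known structure."""

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pytest

from flamingotrack.geo_solar import GeoPoint, InvalidInputError, destination_point, great_circle_km
from flamingotrack import track_segment as ts

COLONY = GeoPoint(44.6053, 12.1747)
T0 = datetime(2015, 8, 10, 0, 0, tzinfo=timezone.utc)


def mk_track(points, bird_id="B1", hatch_year=2015, t0=T0, step_h=2):
    """Track from a list of (lat, lon) at regular 2-h spacing."""
    fixes = [
        ts.Fix(bird_id, t0 + timedelta(hours=step_h * i), GeoPoint(la, lo))
        for i, (la, lo) in enumerate(points)
    ]
    return ts.Track(bird_id, "Comacchio", hatch_year, fixes)


def colony_jitter(n, radius_km=1.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = []
    for _ in range(n):
        pts.append(
            (
                COLONY.lat_deg + rng.uniform(-radius_km, radius_km) / 111.0,
                COLONY.lon_deg + rng.uniform(-radius_km, radius_km) / 80.0,
            )
        )
    return pts


def flight_to(start, bearing, total_km, step_km=100.0):
    """Points along a straight flight, 2-h spacing, step_km per step."""
    pts = []
    cur = start
    travelled = 0.0
    while travelled < total_km:
        d = min(step_km, total_km - travelled)
        cur = destination_point(cur, bearing, d)
        travelled += d
        pts.append((cur.lat_deg, cur.lon_deg))
    return pts, cur


def dwell(center, n, seed=1, radius_km=1.0):
    rng = np.random.default_rng(seed)
    return [
        (
            center.lat_deg + rng.uniform(-radius_km, radius_km) / 111.0,
            center.lon_deg + rng.uniform(-radius_km, radius_km) / 80.0,
        )
        for _ in range(n)
    ]


def migrant_track(total_km=300.0, dwell_days=30, pre_fixes=24, bearing=35.0):
    pre = colony_jitter(pre_fixes)
    flight, dest = flight_to(COLONY, bearing, total_km)
    stay = dwell(dest, dwell_days * 12)
    return mk_track(pre + flight + stay), dest, len(pre)


class TestClassifyStrategy:
    def test_wandering_resident(self):
        rng = np.random.default_rng(3)
        pts = []
        for _ in range(300):
            b = rng.uniform(0, 360)
            d = rng.uniform(0, 40)
            p = destination_point(COLONY, b, d)
            pts.append((p.lat_deg, p.lon_deg))
        assert ts.classify_strategy(mk_track(pts), COLONY) == "resident"

    def test_migrant_before_deadline(self):
        track, _, _ = migrant_track()
        assert ts.classify_strategy(track, COLONY) == "migrant"

    def test_arrival_after_november_first_is_resident(self):
        # crossing 100 km but arriving Nov 3 of the hatch year
        t0 = datetime(2015, 10, 20, 0, 0, tzinfo=timezone.utc)
        pre = colony_jitter(14 * 12)  # at colony until Nov 3
        flight, dest = flight_to(COLONY, 35.0, 300.0)
        stay = dwell(dest, 25 * 12)
        track = mk_track(pre + flight + stay, t0=t0)
        assert ts.classify_strategy(track, COLONY) == "resident"


class TestDetectDeparture:
    def test_departure_is_first_inflight_fix(self):
        track, _, n_pre = migrant_track()
        dep = ts.detect_departure(track, COLONY)
        assert dep.t_utc == track.fixes[n_pre].t_utc

    def test_foraging_loop_ignored(self):
        pre = colony_jitter(12)
        out, far = flight_to(COLONY, 90.0, 60.0, step_km=30.0)
        back, _ = flight_to(far, 270.0, 60.0, step_km=30.0)
        home = colony_jitter(12, seed=5)
        flight, dest = flight_to(COLONY, 35.0, 300.0)
        stay = dwell(dest, 25 * 12)
        track = mk_track(pre + out + back + home + flight + stay)
        dep = ts.detect_departure(track, COLONY)
        expected_idx = len(pre) + len(out) + len(back) + len(home)
        assert dep.t_utc == track.fixes[expected_idx].t_utc

    def test_track_starting_beyond_radius_warns(self):
        start = destination_point(COLONY, 35.0, 150.0)
        flight, dest = flight_to(start, 35.0, 200.0)
        stay = dwell(dest, 25 * 12)
        track = mk_track([(start.lat_deg, start.lon_deg)] + flight + stay)
        with pytest.warns(ts.DataQualityWarning):
            dep = ts.detect_departure(track, COLONY)
        assert dep.t_utc == track.fixes[0].t_utc

    def test_no_excursion_raises(self):
        track = mk_track(colony_jitter(30))
        with pytest.raises(ts.NoDepartureError):
            ts.detect_departure(track, COLONY)


class TestArrivalAndStopovers:
    def test_nonstop_flight_then_long_stay(self):
        track, dest, n_pre = migrant_track()
        dep = ts.detect_departure(track, COLONY)
        arrival, stops = ts.detect_arrival_and_stopovers(track, dep)
        assert stops == []
        assert great_circle_km(arrival.pos, dest) < 20.0

    def test_13h_pause_is_stopover_not_arrival(self):
        pre = colony_jitter(12)
        leg1, mid = flight_to(COLONY, 35.0, 200.0)
        pause = dwell(mid, 7)  # 7 fixes = 12-14 h dwell
        leg2, dest = flight_to(mid, 35.0, 200.0)
        stay = dwell(dest, 25 * 12)
        track = mk_track(pre + leg1 + pause + leg2 + stay)
        dep = ts.detect_departure(track, COLONY)
        arrival, stops = ts.detect_arrival_and_stopovers(track, dep)
        assert len(stops) == 1
        assert stops[0].dwell_h >= 12.0
        assert great_circle_km(arrival.pos, dest) < 20.0

    def test_19_day_stay_is_stopover_not_nonbreeding(self):
        pre = colony_jitter(12)
        leg1, mid = flight_to(COLONY, 35.0, 200.0)
        pause = dwell(mid, 19 * 12)  # 19 days < the 20-day rule
        leg2, dest = flight_to(mid, 35.0, 200.0)
        stay = dwell(dest, 25 * 12)
        track = mk_track(pre + leg1 + pause + leg2 + stay)
        dep = ts.detect_departure(track, COLONY)
        arrival, stops = ts.detect_arrival_and_stopovers(track, dep)
        assert any(s.dwell_h >= 18 * 24 for s in stops)
        assert great_circle_km(arrival.pos, dest) < 20.0

    def test_open_ended_event(self):
        pre = colony_jitter(12)
        flight, dest = flight_to(COLONY, 35.0, 300.0)
        stay = dwell(dest, 5 * 12)  # data end after 5 days
        track = mk_track(pre + flight + stay)
        dep = ts.detect_departure(track, COLONY)
        with pytest.raises(ts.OpenEndedEventError):
            ts.detect_arrival_and_stopovers(track, dep)


class TestSegmentKinematics:
    def test_speed_from_distance_and_time(self):
        p2 = destination_point(COLONY, 90.0, 100.0)
        track = mk_track([(COLONY.lat_deg, COLONY.lon_deg), (p2.lat_deg, p2.lon_deg)])
        segs = ts.segment_kinematics(track.fixes)
        assert segs[0].speed_kmh == pytest.approx(50.0, rel=1e-6)
        assert segs[0].cumulative_km == 0.0

    def test_exclude_final_count(self):
        flight, _ = flight_to(COLONY, 0.0, 500.0, step_km=50.0)
        track = mk_track(flight)
        n = len(track.fixes)
        assert len(ts.segment_kinematics(track.fixes, exclude_final=True)) == n - 2

    def test_cumulative_distance_non_decreasing_and_consistent(self):
        flight, _ = flight_to(COLONY, 10.0, 400.0, step_km=80.0)
        track = mk_track(flight)
        segs = ts.segment_kinematics(track.fixes)
        cums = [s.cumulative_km for s in segs]
        assert all(b >= a for a, b in zip(cums, cums[1:]))
        assert cums[-1] == pytest.approx(sum(s.dist_km for s in segs[:-1]), abs=1e-9)

    def test_invalid_ordering_rejected(self):
        f1 = ts.Fix("B", T0, COLONY)
        f2 = ts.Fix("B", T0, GeoPoint(45, 12))
        with pytest.raises(InvalidInputError):
            ts.segment_kinematics([f1, f2])


class TestEventSummary:
    def test_summary_internal_consistency(self):
        track, dest, _ = migrant_track(total_km=400.0)
        event = ts.extract_event(track, COLONY)
        s = ts.summarize_event(event)
        assert s["mean_speed_kmh"] <= s["max_speed_kmh"]
        straight = great_circle_km(event.departure_fix.pos, event.arrival_fix.pos)
        assert s["total_distance_km"] >= straight - 1e-6
        segs = ts.segment_kinematics(
            [event.departure_fix] + list(event.in_flight) + [event.arrival_fix]
        )
        assert s["total_distance_km"] == pytest.approx(
            sum(x.dist_km for x in segs), abs=1e-6
        )
        dur = (event.arrival_fix.t_utc - event.departure_fix.t_utc).total_seconds() / 3600
        assert s["duration_h"] == pytest.approx(dur, abs=1e-9)


def test_movebank_round_trip(tmp_path):
    track, _, _ = migrant_track(total_km=200.0, dwell_days=2)
    path = tmp_path / "fixes.csv"
    ts.write_movebank_csv([track], path)
    back = ts.read_movebank_csv(path, {"B1": "Comacchio"}, {"B1": 2015})[0]
    assert back.bird_id == track.bird_id
    assert len(back.fixes) == len(track.fixes)
    assert back.fixes[10].t_utc == track.fixes[10].t_utc
    assert back.fixes[10].pos.lat_deg == pytest.approx(track.fixes[10].pos.lat_deg)
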