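"""The five analyses: dataset builders plus model specifications.

1. *Departure probability* — case-control binomial GLMM: the departure fix
   (label 1) against every nightly-window fix in the 72 h before departure
   (label 0), weather evaluated AT THE COLONY, flight direction = the
   departure-to-arrival bearing; random intercept per bird; optional
   tailwind x migration-distance interaction.
2. *Flight speed* — Gaussian LMM on consecutive-segment speeds (final
   segment excluded), weather at the moving bird with segment-wise flight
   direction, quadratic humidity and cumulative distance; optional
   sex x tailwind interaction.
3. *Phenology* — LMs of departure day-of-year on sex, colony (+ sex x
   colony), year and migration distance, with each biometric/SMI variant
   added one at a time to avoid collinearity.
4. *Migration distance* — LM of total event distance on route-averaged
   weather plus sex, colony, departure date.
5. *Direction vs seasonal wind* — in circular_stats.

The case-control builder is deterministic given its inputs and reports the
rows it had to drop for missing weather coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from .geo_solar import (
    GeoPoint,
    day_of_year,
    hours_after_sunset,
    italian_utc_offset_minutes,
)
from .inference_core import (
    Cat,
    Cont,
    FitResult,
    Interaction,
    ModelSpec,
    fit_glmm_binomial,
    fit_lm,
    fit_lmm,
)
from .track_segment import MigrationEvent, segment_kinematics
from .weather_field import (
    ExtrapolationError,
    annotate_points,
    crosswind_kmh,
    tailwind_kmh,
)

WEATHER_COVARIATES = [
    "tailwind", "crosswind", "wind_speed", "pressure", "rel_humidity",
    "cloud_low", "cloud_medium", "cloud_high", "temperature", "rain",
]

#: nightly case-control window, local civil hours (both endpoints printed)
WINDOW_START_H = 16.0
WINDOW_END_H = 2.0
WINDOW_DAYS = 3


def _in_nightly_window(t_utc) -> bool:
    off = italian_utc_offset_minutes(t_utc.date())
    lt = t_utc + timedelta(minutes=off)
    h = lt.hour + lt.minute / 60.0 + lt.second / 3600.0
    return h >= WINDOW_START_H or h <= WINDOW_END_H


def _annotate(grids, lats, lons, times_utc) -> pd.DataFrame:
    """Interpolated weather columns renamed to the analysis vocabulary."""
    def _naive_utc(t):
        ts = pd.Timestamp(t)
        if ts.tzinfo is not None:
            ts = ts.tz_convert("UTC").tz_localize(None)
        return np.datetime64(ts, "ns")

    t_np = np.array([_naive_utc(t) for t in times_utc])
    df = annotate_points(grids, np.asarray(lats, float), np.asarray(lons, float), t_np)
    return df.rename(columns={"precipitation": "rain"})


@dataclass
class CaseControlResult:
    table: pd.DataFrame
    n_dropped_missing_weather: int


def build_departure_cases(
    events: dict,
    tracks: dict,
    grids: dict,
    colonies: dict,
    biometrics: pd.DataFrame,
) -> CaseControlResult:
    """Case-control table for the departure GLMM.

    events: bird_id -> MigrationEvent; tracks: bird_id -> Track;
    colonies: colony_id -> GeoPoint.  Label-0 rows are every fix whose local
    time falls in [16:00, 02:00] within the 72 h before the departure fix;
    the single label-1 row is the departure fix, with weather evaluated at
    the colony in both cases.  Tailwind/crosswind use the route
    (departure -> arrival) bearing.
    """
    meta = biometrics.set_index("bird_id")
    rows = []
    dropped = 0
    for bird_id, ev in events.items():
        track = tracks[bird_id]
        colony_pt = colonies[track.colony_id]
        route_bearing = ev.destination_bearing_deg
        dep_t = ev.departure_fix.t_utc
        window_start = dep_t - timedelta(hours=24 * WINDOW_DAYS)
        cand = [
            f for f in track.fixes
            if window_start <= f.t_utc < dep_t and _in_nightly_window(f.t_utc)
        ]
        times = [f.t_utc for f in cand] + [dep_t]
        labels = [0] * len(cand) + [1]
        for t, label in zip(times, labels):
            try:
                w = _annotate(
                    grids, [colony_pt.lat_deg], [colony_pt.lon_deg], [t]
                ).iloc[0]
            except ExtrapolationError:
                dropped += 1
                continue
            off = italian_utc_offset_minutes(t.date())
            rows.append(
                {
                    "bird_id": bird_id,
                    "t_utc": t,
                    "label": label,
                    "tailwind": tailwind_kmh(w["wind_speed_ms"],
                                             w["wind_dir_to_deg"] if np.isfinite(w["wind_dir_to_deg"]) else 0.0,
                                             route_bearing),
                    "crosswind": crosswind_kmh(w["wind_speed_ms"],
                                               w["wind_dir_to_deg"] if np.isfinite(w["wind_dir_to_deg"]) else 0.0,
                                               route_bearing),
                    "wind_speed": w["wind_speed_ms"] * 3.6,
                    "pressure": w["pressure"],
                    "rel_humidity": w["rel_humidity"],
                    "cloud_low": w["cloud_low"],
                    "cloud_medium": w["cloud_medium"],
                    "cloud_high": w["cloud_high"],
                    "temperature": w["temperature"],
                    "rain": w["rain"],
                    "hours_after_sunset": hours_after_sunset(t, colony_pt, off),
                    "colony": track.colony_id,
                    "year": str(track.hatch_year),
                    "sex": meta.loc[bird_id, "sex"],
                    "migration_distance_km": ev.total_distance_km,
                }
            )
    table = pd.DataFrame(rows).sort_values(["bird_id", "t_utc"]).reset_index(drop=True)
    if dropped:
        warnings.warn(f"dropped {dropped} case-control rows for missing weather coverage")
    return CaseControlResult(table, dropped)


def departure_model_terms(table: pd.DataFrame, interaction: bool = False) -> list:
    """Table-1 term list; factors with a single observed level are omitted
    up front (they would be aliased anyway)."""
    terms = [
        Cont("crosswind"), Cont("wind_speed"), Cont("tailwind"),
        Cont("pressure"), Cont("rel_humidity"),
        Cont("cloud_medium"), Cont("cloud_high"), Cont("cloud_low"),
        Cont("temperature"), Cont("rain"),
    ]
    if table["colony"].nunique() > 1:
        terms.append(Cat("colony", ref="Comacchio" if "Comacchio" in set(table["colony"]) else None))
    if table["year"].nunique() > 1:
        terms.append(Cat("year", ref="2015" if "2015" in set(table["year"]) else None))
    if table["sex"].nunique() > 1:
        terms.append(Cat("sex", ref="F"))
    terms.append(Cont("hours_after_sunset", quadratic=True))
    if interaction:
        terms.append(Cont("migration_distance_km"))
        terms.append(Interaction(Cont("tailwind"), Cont("migration_distance_km")))
    return terms


def fit_departure_model(table: pd.DataFrame) -> FitResult:
    """Binomial random-intercept GLMM mirroring the departure-probability
    model (weather + colony/year/sex + linear and quadratic hours after
    sunset; bird as random intercept)."""
    spec = ModelSpec("label", departure_model_terms(table), "binomial", group="bird_id")
    return fit_glmm_binomial(spec, table)


def fit_departure_distance_interaction(table: pd.DataFrame) -> FitResult:
    """Departure GLMM with the tailwind x migration-distance interaction."""
    spec = ModelSpec(
        "label", departure_model_terms(table, interaction=True), "binomial",
        group="bird_id",
    )
    return fit_glmm_binomial(spec, table)


def build_speed_table(
    events: dict, tracks: dict, grids: dict, biometrics: pd.DataFrame
) -> pd.DataFrame:
    """Segment-speed dataset: one row per consecutive in-flight segment
    (final segment excluded), weather interpolated at the segment's start
    fix, tailwind/crosswind along the segment bearing, and the cumulative
    distance travelled up to that fix.  Segments slower than the in-flight
    threshold (stopover dwells en route) are not flight and are excluded."""
    from .track_segment import DEFAULT_FLIGHT_SPEED_KMH

    meta = biometrics.set_index("bird_id")
    rows = []
    for bird_id, ev in events.items():
        track = tracks[bird_id]
        journey = [ev.departure_fix] + list(ev.in_flight) + [ev.arrival_fix]
        segs = segment_kinematics(journey, exclude_final=True)
        for s in segs:
            if not np.isfinite(s.bearing_deg) or s.speed_kmh < DEFAULT_FLIGHT_SPEED_KMH:
                continue
            try:
                w = _annotate(
                    grids, [s.from_fix.pos.lat_deg], [s.from_fix.pos.lon_deg],
                    [s.from_fix.t_utc],
                ).iloc[0]
            except ExtrapolationError:
                continue
            wdir = w["wind_dir_to_deg"] if np.isfinite(w["wind_dir_to_deg"]) else 0.0
            rows.append(
                {
                    "bird_id": bird_id,
                    "t_utc": s.from_fix.t_utc,
                    "speed_kmh": s.speed_kmh,
                    "tailwind": tailwind_kmh(w["wind_speed_ms"], wdir, s.bearing_deg),
                    "crosswind": crosswind_kmh(w["wind_speed_ms"], wdir, s.bearing_deg),
                    "cloud_low": w["cloud_low"],
                    "cloud_medium": w["cloud_medium"],
                    "cloud_high": w["cloud_high"],
                    "temperature": w["temperature"],
                    "rel_humidity": w["rel_humidity"],
                    "rain": w["rain"],
                    "pressure": w["pressure"],
                    "cumulative_km": s.cumulative_km,
                    "colony": track.colony_id,
                    "year": str(track.hatch_year),
                    "sex": meta.loc[bird_id, "sex"],
                }
            )
    return pd.DataFrame(rows)


def fit_speed_model(table: pd.DataFrame, sex_tailwind_interaction: bool = False) -> FitResult:
    """Gaussian LMM for consecutive speeds (Table-2 structure): sex, year,
    colony, weather (quadratic humidity), quadratic cumulative distance,
    bird random intercept.  The variant focuses on sex x tailwind."""
    terms = [Cat("sex", ref="F")]
    if table["year"].nunique() > 1:
        terms.append(Cat("year", ref="2015" if "2015" in set(table["year"]) else None))
    terms += [
        Cont("crosswind"), Cont("tailwind"),
        Cont("cloud_high"), Cont("cloud_low"), Cont("cloud_medium"),
        Cont("temperature"), Cont("rel_humidity", quadratic=True),
        Cont("rain"), Cont("pressure"),
    ]
    if table["colony"].nunique() > 1:
        terms.append(Cat("colony", ref="Comacchio" if "Comacchio" in set(table["colony"]) else None))
    terms.append(Cont("cumulative_km", quadratic=True))
    if sex_tailwind_interaction:
        terms.append(Interaction(Cat("sex", ref="F"), Cont("tailwind")))
    spec = ModelSpec("speed_kmh", terms, "gaussian", group="bird_id")
    return fit_lmm(spec, table)


def speed_profile_vertex_km(fit: FitResult) -> float:
    """Cumulative distance (km, raw scale) at which the fitted concave speed
    profile peaks: vertex -b1/(2 b2) back-transformed through the scaling."""
    b1 = fit.params["cumulative_km"]
    b2 = fit.params["cumulative_km^2"]
    mu, sd = fit.scaling["cumulative_km"]
    return float(mu + sd * (-b1 / (2.0 * b2)))


def build_phenology_table(
    events: dict, tracks: dict, biometrics: pd.DataFrame
) -> pd.DataFrame:
    """One row per migrant: departure day-of-year (local civil date), sex,
    colony, year, total distance and the biometrics."""
    from .condition import add_smi

    meta = add_smi(biometrics).set_index("bird_id")
    rows = []
    for bird_id, ev in events.items():
        t = ev.departure_fix.t_utc
        off = italian_utc_offset_minutes(t.date())
        local_date = (t + timedelta(minutes=off)).date()
        rows.append(
            {
                "bird_id": bird_id,
                "departure_doy": day_of_year(local_date),
                "sex": meta.loc[bird_id, "sex"],
                "colony": tracks[bird_id].colony_id,
                "year": str(tracks[bird_id].hatch_year),
                "distance_km": ev.total_distance_km,
                "tarsus_mm": meta.loc[bird_id, "tarsus_mm"],
                "mass_g": meta.loc[bird_id, "mass_g"],
                "wing_mm": meta.loc[bird_id, "wing_mm"],
                "smi_g": meta.loc[bird_id, "smi_g"],
            }
        )
    return pd.DataFrame(rows)


def fit_phenology_models(table: pd.DataFrame) -> dict:
    """LMs of departure day-of-year; the base model uses sex, colony,
    sex x colony, year and distance, and each biometric/SMI is then added
    individually (to avoid collinearity among size measures)."""
    base_terms: list = [Cat("sex", ref="F")]
    if table["colony"].nunique() > 1:
        base_terms += [Cat("colony"), Interaction(Cat("sex", ref="F"), Cat("colony"))]
    if table["year"].nunique() > 1:
        base_terms.append(Cat("year"))
    base_terms.append(Cont("distance_km"))
    fits = {"base": fit_lm(ModelSpec("departure_doy", base_terms, "gaussian"), table)}
    for biom in ("tarsus_mm", "mass_g", "wing_mm", "smi_g"):
        spec = ModelSpec("departure_doy", base_terms + [Cont(biom)], "gaussian")
        fits[biom] = fit_lm(spec, table)
    return fits


def build_distance_table(
    events: dict, tracks: dict, grids: dict, biometrics: pd.DataFrame
) -> pd.DataFrame:
    """One row per migrant: total event distance and weather covariates
    averaged (unweighted) over the annotated in-flight fixes of the route;
    events with fewer than two annotated fixes are dropped with a report."""
    meta = biometrics.set_index("bird_id")
    rows = []
    n_dropped = 0
    for bird_id, ev in events.items():
        fixes = [ev.departure_fix] + list(ev.in_flight)
        route_bearing = ev.destination_bearing_deg
        ann = []
        for f in fixes:
            try:
                w = _annotate(grids, [f.pos.lat_deg], [f.pos.lon_deg], [f.t_utc]).iloc[0]
            except ExtrapolationError:
                continue
            wdir = w["wind_dir_to_deg"] if np.isfinite(w["wind_dir_to_deg"]) else 0.0
            ann.append(
                {
                    "tailwind": tailwind_kmh(w["wind_speed_ms"], wdir, route_bearing),
                    "crosswind": crosswind_kmh(w["wind_speed_ms"], wdir, route_bearing),
                    "wind_speed": w["wind_speed_ms"] * 3.6,
                    "temperature": w["temperature"],
                    "rel_humidity": w["rel_humidity"],
                    "pressure": w["pressure"],
                    "rain": w["rain"],
                    "cloud_low": w["cloud_low"],
                    "cloud_medium": w["cloud_medium"],
                    "cloud_high": w["cloud_high"],
                }
            )
        if len(ann) < 2:
            n_dropped += 1
            continue
        row = pd.DataFrame(ann).mean().to_dict()
        t = ev.departure_fix.t_utc
        off = italian_utc_offset_minutes(t.date())
        row.update(
            {
                "bird_id": bird_id,
                "distance_km": ev.total_distance_km,
                "sex": meta.loc[bird_id, "sex"],
                "colony": tracks[bird_id].colony_id,
                "departure_doy": day_of_year((t + timedelta(minutes=off)).date()),
            }
        )
        rows.append(row)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} events with < 2 annotated fixes")
    return pd.DataFrame(rows)


def fit_distance_model(table: pd.DataFrame) -> FitResult:
    """LM of total migration distance on route-averaged weather plus sex,
    colony and departure date."""
    if table["distance_km"].nunique() <= 1:
        raise ValueError("zero-variance response: all events identical distance")
    terms: list = [
        Cont("tailwind"), Cont("crosswind"), Cont("wind_speed"),
        Cont("temperature"), Cont("rel_humidity"), Cont("pressure"),
        Cont("rain"), Cont("cloud_low"), Cont("cloud_medium"), Cont("cloud_high"),
        Cat("sex", ref="F"), Cont("departure_doy"),
    ]
    if table["colony"].nunique() > 1:
        terms.append(Cat("colony"))
    spec = ModelSpec("distance_km", terms, "gaussian")
    return fit_lm(spec, table)
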