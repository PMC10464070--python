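"""Ground-truthed synthetic datasets emulating the study's data structure.

The generator produces, from one seed: three Mediterranean colonies at the
published coordinates, ~40 juveniles (sex ratio 11F:29M), sex/colony-
structured biometrics, reanalysis-style weather grids (0.25 deg / 1 h
atmospheric fields, 0.75 deg / 6 h cloud layers) with colony-specific
prevailing-wind regimes, and 2-h GPS fix streams in which

* migration propensity rises with body condition (logistic in SMI),
* departures are nocturnal and wind-triggered: at every 2-h step inside the
  local 16:00-02:00 window a waiting migrant departs with probability
  logit^-1 of the published standardized hazard coefficients applied to
  within-simulation-standardized tailwind and hours-after-sunset, and
* in-flight speed responds to sex, segment tailwind and cumulative distance
  with a concave profile peaking near 400 km.

Every stochastic choice is recorded in a TruthRecord so segmentation and
model-recovery tests can compare against ground truth.  All randomness
derives from one seed via numpy SeedSequence spawning.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter
from scipy.special import expit

from .geo_solar import (
    GeoPoint,
    destination_point,
    great_circle_km,
    hours_after_sunset,
    initial_bearing_deg,
    italian_utc_offset_minutes,
)
from .track_segment import Fix, Track, write_movebank_csv
from .weather_field import WeatherGrid, interpolate_at, tailwind_kmh, wind_speed_dir, write_netcdf

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Destination:
    name: str
    bearing_deg: float
    distance_km: float
    prob: float


@dataclass
class WindRegime:
    dir_to_deg: float  # blowing-toward bearing
    speed_ms: float
    weight: float


@dataclass
class ColonyConfig:
    colony_id: str
    lat: float
    lon: float
    n_birds: int
    destinations: list
    wind_regimes: list
    # mean days after window start before birds at this colony are ready to
    # leave (drives the colony phenology offsets seen in the study)
    readiness_offset_days: float = 0.0


@dataclass
class SimConfig:
    """The stated world.  Defaults encode the study's published structure:
    published colony coordinates, 40 birds (11F:29M), hazard coefficients
    from the departure model (intercept -4.97, tailwind 1.41, hours after
    sunset 4.37, quadratic -2.52), and speed coefficients from the speed
    model (sex(M) -10.73, tailwind 8.52, cumulative distance 8.2 linear /
    -8.79 quadratic) on the standardized scale."""

    seed: int = 0
    year: int = 2015
    window_start: str = "2015-08-01"
    weather_end: str = "2015-11-15"
    fixes_end: str = "2015-12-01"
    fix_interval_h: int = 2
    sex_ratio_f: float = 11.0 / 40.0
    colonies: list = field(default_factory=lambda: _default_colonies())

    # propensity: P(migrate) = expit(a + b * z_SMI)
    propensity_intercept: float = 1.4
    propensity_slope: float = 0.9

    # departure hazard, standardized scale
    hazard_intercept: float = -4.97
    hazard_tailwind: float = 1.41
    hazard_hours_after_sunset: float = 4.37
    hazard_hours_after_sunset_sq: float = -2.52

    # in-flight speed model (km/h), standardized covariates; the intercept is
    # the published standardized-scale intercept (reference female at
    # covariate means)
    speed_intercept_kmh: float = 72.05
    speed_sex_m: float = -10.73
    speed_tailwind: float = 8.52
    speed_cumdist: float = 8.2
    speed_cumdist_sq: float = -8.79
    speed_resid_sd: float = 8.0
    speed_bird_sd: float = 5.0
    # standardization constants for cumulative distance: chosen a priori so
    # the concave profile peaks at ~400 km (= mu + sd * (-b1 / (2 b2)))
    cumdist_std_mean_km: float = 300.0
    cumdist_std_sd_km: float = 214.3

    # biometrics: per-sex means/SDs with colony offsets
    tarsus_mean_mm: dict = field(default_factory=lambda: {"M": 275.0, "F": 247.0})
    tarsus_sd_mm: float = 12.0
    mass_mean_g: dict = field(default_factory=lambda: {"M": 3300.0, "F": 2650.0})
    mass_sd_g: float = 300.0
    wing_mean_mm: dict = field(default_factory=lambda: {"M": 480.0, "F": 450.0})
    wing_sd_mm: float = 18.0
    colony_mass_offset_g: dict = field(
        default_factory=lambda: {"Comacchio": 150.0, "Margherita": 0.0, "Molentargius": -100.0}
    )

    # behaviour
    colony_radius_jitter_km: float = 0.8
    resident_sd_km: float = 3.0
    stopover_prob: float = 0.25
    stopover_min_total_km: float = 350.0
    stopover_dwell_h: float = 14.0
    force_departure_after: str = "2015-10-20"
    sex_readiness_offset_f_days: float = 10.0
    readiness_sd_days: float = 5.0

    # weather domain (auto-covers colonies + destinations)
    lat_min: float = 34.0
    lat_max: float = 47.0
    lon_min: float = 4.5
    lon_max: float = 18.5

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "colonies" in d:
            cols = []
            for c in d["colonies"]:
                c = dict(c)
                c["destinations"] = [Destination(**x) for x in c["destinations"]]
                c["wind_regimes"] = [WindRegime(**x) for x in c["wind_regimes"]]
                cols.append(ColonyConfig(**c))
            d["colonies"] = cols
        return cls(**d)


def _default_colonies() -> list:
    """Three Italian colonies at the published coordinates, with regional
    prevailing-wind regimes (blowing-toward convention) and destination
    mixtures chosen so wind and departure directions are aligned at
    Molentargius (Mistral -> Tunisia) and anti-aligned at Margherita di
    Savoia (Mistral vs northward departures)."""
    return [
        ColonyConfig(
            colony_id="Molentargius",
            lat=39.2282, lon=9.1526,  # 39 13'41.7"N 9 09'09.3"E
            n_birds=16,
            destinations=[
                Destination("Tunisia", 175.0, 420.0, 0.65),
                Destination("France", 325.0, 540.0, 0.15),
                Destination("Spain", 250.0, 400.0, 0.10),
                Destination("Margherita", 75.0, 600.0, 0.10),
            ],
            wind_regimes=[
                WindRegime(150.0, 8.0, 0.6),   # Mistral-like, toward SE
                WindRegime(315.0, 6.0, 0.4),   # Scirocco-like, toward NW
            ],
            readiness_offset_days=5.0,
        ),
        ColonyConfig(
            colony_id="Comacchio",
            lat=44.6053, lon=12.1747,  # 44 36'19.2"N 12 10'28.8"E
            n_birds=11,
            destinations=[
                Destination("Venice", 35.0, 115.0, 0.60),
                Destination("Sardinia", 195.0, 560.0, 0.15),
                Destination("Corsica", 205.0, 450.0, 0.10),
                Destination("France", 250.0, 480.0, 0.15),
            ],
            wind_regimes=[
                WindRegime(225.0, 6.0, 0.5),   # Bora-like, toward SW
                WindRegime(270.0, 5.0, 0.3),   # Levante-like, toward W
                WindRegime(45.0, 3.5, 0.2),
            ],
            readiness_offset_days=20.0,
        ),
        ColonyConfig(
            colony_id="Margherita",
            lat=41.3987, lon=16.0404,  # 41 23'55.4"N 16 02'25.5"E
            n_birds=13,
            destinations=[
                Destination("PoDelta", 335.0, 420.0, 0.50),
                Destination("Sardinia", 255.0, 500.0, 0.20),
                Destination("Tuscany", 300.0, 400.0, 0.15),
                Destination("Tunisia", 195.0, 700.0, 0.10),
                Destination("Venice", 340.0, 490.0, 0.05),
            ],
            wind_regimes=[
                WindRegime(135.0, 7.0, 0.5),   # Mistral-like, toward SE (dominant)
                WindRegime(90.0, 4.0, 0.25),
                WindRegime(315.0, 6.0, 0.25),  # Scirocco-like, toward NW
            ],
            readiness_offset_days=40.0,
        ),
    ]


@dataclass
class TruthRecord:
    """Per-bird ground truth plus the generative coefficients."""

    birds: dict  # bird_id -> dict(strategy, departure_utc, arrival_utc, ...)
    coefficients: dict
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"birds": self.birds, "coefficients": self.coefficients, "seed": self.seed},
            indent=1, default=str,
        ))

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return cls(d["birds"], d["coefficients"], d["seed"])


# ---------------------------------------------------------------------------
# Weather simulation
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, phi: float = 0.95, sd: float = 1.0) -> np.ndarray:
    eps = rng.normal(0.0, sd * np.sqrt(1 - phi ** 2), n)
    return lfilter([1.0], [1.0, -phi], eps)


def _regime_series(rng, regimes, n_hours: int, block_h: int = 6):
    """Markov switching between wind regimes at 6-h blocks, linearly
    interpolated to hourly u/v with a diurnal modulation and AR(1) noise."""
    n_blocks = n_hours // block_h + 2
    weights = np.array([r.weight for r in regimes], dtype=float)
    weights /= weights.sum()
    states = np.zeros(n_blocks, dtype=int)
    states[0] = rng.choice(len(regimes), p=weights)
    # mean dwell ~ 6 blocks (36 h): stay prob 5/6, else redraw by weight
    for k in range(1, n_blocks):
        if rng.random() < 1.0 / 6.0:
            states[k] = rng.choice(len(regimes), p=weights)
        else:
            states[k] = states[k - 1]
    dirs = np.array([r.dir_to_deg for r in regimes])
    spds = np.array([r.speed_ms for r in regimes])
    block_u = spds[states] * np.sin(np.radians(dirs[states]))
    block_v = spds[states] * np.cos(np.radians(dirs[states]))
    t_blocks = np.arange(n_blocks) * block_h
    t_hours = np.arange(n_hours)
    u = np.interp(t_hours, t_blocks, block_u)
    v = np.interp(t_hours, t_blocks, block_v)
    diurnal = 1.0 + 0.25 * np.sin(2 * np.pi * (t_hours % 24 - 15) / 24.0)
    u = u * diurnal + _ar1(rng, n_hours, 0.9, 1.5)
    v = v * diurnal + _ar1(rng, n_hours, 0.9, 1.5)
    return u, v


def simulate_weather(config: SimConfig, rng: np.random.Generator | None = None) -> dict:
    """All nine variables on their native grids (0.25 deg/1 h; clouds
    0.75 deg/6 h).  Wind is a space-weighted mixture of per-colony regime
    series, so each colony feels its own prevailing winds."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    t0 = np.datetime64(config.window_start, "ns")
    t1 = np.datetime64(config.weather_end, "ns")
    times = np.arange(t0, t1 + np.timedelta64(1, "h"), np.timedelta64(1, "h"))
    n_t = len(times)
    lats = np.arange(config.lat_min, config.lat_max + 1e-9, 0.25)
    lons = np.arange(config.lon_min, config.lon_max + 1e-9, 0.25)
    LA, LO = np.meshgrid(lats, lons, indexing="ij")

    # per-colony regime series + background, blended by Gaussian kernels
    kernels = []
    series = []
    for col in config.colonies:
        d2 = ((LA - col.lat) * 111.0) ** 2 + ((LO - col.lon) * 111.0 * np.cos(np.radians(col.lat))) ** 2
        kernels.append(np.exp(-d2 / (2 * 250.0 ** 2)))
        series.append(_regime_series(rng, col.wind_regimes, n_t))
    bg_u = _ar1(rng, n_t, 0.95, 2.0)
    bg_v = _ar1(rng, n_t, 0.95, 2.0)
    w_bg = 0.25
    denom = w_bg + sum(kernels)
    u = np.zeros((n_t, len(lats), len(lons)))
    v = np.zeros_like(u)
    for k, (su, sv) in zip(kernels, series):
        u += su[:, None, None] * k[None, :, :]
        v += sv[:, None, None] * k[None, :, :]
    u = (u + w_bg * bg_u[:, None, None]) / denom[None, :, :]
    v = (v + w_bg * bg_v[:, None, None]) / denom[None, :, :]

    hours = (times - t0) / np.timedelta64(1, "h")
    day = hours / 24.0
    hod = hours % 24
    diurnal = np.sin(2 * np.pi * (hod - 15) / 24.0)
    temp_t = 4.0 * diurnal - 0.07 * day + _ar1(rng, n_t, 0.95, 1.2)
    temp = 26.0 - 0.45 * (LA[None, :, :] - 34.0) + temp_t[:, None, None]
    # rain spells plus a small everywhere-positive drizzle floor, as in
    # reanalysis total-precipitation fields (never exactly zero)
    rain_t = np.maximum(0.0, _ar1(rng, n_t, 0.9, 1.0) - 1.2) * 2.0
    drizzle = 0.02 + 0.02 * np.abs(_ar1(rng, n_t, 0.8, 1.0))
    rain = (rain_t + drizzle)[:, None, None] * (1.0 + 0.05 * (LA[None, :, :] - 40.0))
    rain = np.maximum(rain, 0.0)
    rh_t = 15.0 * _ar1(rng, n_t, 0.93, 1.0) - 4.0 * diurnal
    rh = np.clip(68.0 + rh_t[:, None, None] + 0.4 * (LA[None, :, :] - 40.0), 25.0, 100.0)
    pres_t = 450.0 * _ar1(rng, n_t, 0.97, 1.0)
    pres = 101300.0 + pres_t[:, None, None] - 40.0 * (LA[None, :, :] - 40.0)

    grids = {
        "wind_u": WeatherGrid("wind_u", times, lats, lons, u),
        "wind_v": WeatherGrid("wind_v", times, lats, lons, v),
        "temperature": WeatherGrid("temperature", times, lats, lons, temp),
        "precipitation": WeatherGrid("precipitation", times, lats, lons, rain),
        "rel_humidity": WeatherGrid("rel_humidity", times, lats, lons, rh),
        "pressure": WeatherGrid("pressure", times, lats, lons, pres),
    }

    # cloud layers: 0.75 deg, 6-hourly
    c_times = np.arange(t0, t1 + np.timedelta64(1, "h"), np.timedelta64(6, "h"))
    c_lats = np.arange(config.lat_min, config.lat_max + 1e-9, 0.75)
    c_lons = np.arange(config.lon_min, config.lon_max + 1e-9, 0.75)
    CLA = np.meshgrid(c_lats, c_lons, indexing="ij")[0]
    for name in ("cloud_low", "cloud_medium", "cloud_high"):
        ct = _ar1(rng, len(c_times), 0.85, 0.18)
        vals = np.clip(0.35 + ct[:, None, None] + 0.01 * (CLA[None, :, :] - 40.0), 0.0, 1.0)
        grids[name] = WeatherGrid(name, c_times, c_lats, c_lons, vals)
    return grids


# ---------------------------------------------------------------------------
# Birds
# ---------------------------------------------------------------------------

def simulate_birds(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Biometrics table with the latent migration decision.

    migrate ~ Bernoulli(expit(a + b * z_SMI)) with SMI standardized within
    the sample: better-conditioned juveniles are more likely to migrate."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    rows = []
    i = 0
    for col in config.colonies:
        for _ in range(col.n_birds):
            sex = "F" if rng.random() < config.sex_ratio_f else "M"
            mass_off = config.colony_mass_offset_g.get(col.colony_id, 0.0)
            tarsus = rng.normal(config.tarsus_mean_mm[sex] + mass_off / 50.0, config.tarsus_sd_mm)
            mass = rng.normal(config.mass_mean_g[sex] + mass_off, config.mass_sd_g)
            wing = rng.normal(config.wing_mean_mm[sex] + mass_off / 15.0, config.wing_sd_mm)
            rows.append(
                {
                    "bird_id": f"SYN{i:03d}",
                    "sex": sex,
                    "colony": col.colony_id,
                    "year": config.year,
                    "tarsus_mm": round(float(max(tarsus, 180.0))),
                    "mass_g": round(float(max(mass, 1500.0)) / 50.0) * 50.0,
                    "wing_mm": round(float(max(wing, 300.0))),
                }
            )
            i += 1
    birds = pd.DataFrame(rows)
    ref = {s: config.tarsus_mean_mm[s] for s in ("M", "F")}
    smi = birds["mass_g"] * np.array([ref[s] for s in birds["sex"]]) / birds["tarsus_mm"]
    z = (smi - smi.mean()) / smi.std(ddof=1)
    p = expit(config.propensity_intercept + config.propensity_slope * z)
    birds["migrate"] = (rng.random(len(birds)) < p).astype(int)
    return birds


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def _km_to_deg(lat: float):
    return 1.0 / 111.0, 1.0 / (111.0 * np.cos(np.radians(lat)))


def _eligible_mask(times_utc: pd.DatetimeIndex) -> np.ndarray:
    """Local civil time inside the nightly window [16:00, 24:00) u [00:00, 02:00]."""
    out = np.zeros(len(times_utc), dtype=bool)
    for i, t in enumerate(times_utc):
        off = italian_utc_offset_minutes(t.date())
        lt = t + pd.Timedelta(minutes=off)
        h = lt.hour + lt.minute / 60.0
        out[i] = (h >= 16.0) or (h <= 2.0)
    return out


def _colony_window_moments(config, colony, route_bearing, grids, fix_times):
    """Mean/SD of colony tailwind (toward the route bearing) and hours after
    sunset over all eligible 2-h steps of the season, used to standardize
    the hazard covariates within the simulation."""
    idx = pd.DatetimeIndex(fix_times)
    idx = idx[idx <= pd.Timestamp(config.weather_end, tz="UTC")]
    mask = _eligible_mask(idx)
    t_el = idx[mask]
    p = GeoPoint(colony.lat, colony.lon)
    tq = np.array([np.datetime64(t.tz_localize(None) if t.tzinfo else t, "ns") for t in t_el])
    lats = np.full(len(tq), colony.lat)
    lons = np.full(len(tq), colony.lon)
    u = interpolate_at(grids["wind_u"], lats, lons, tq)
    v = interpolate_at(grids["wind_v"], lats, lons, tq)
    speed, wdir = wind_speed_dir(u, v)
    tw = tailwind_kmh(speed, np.where(np.isfinite(wdir), wdir, 0.0), route_bearing)
    has = np.array([
        hours_after_sunset(t.to_pydatetime().replace(tzinfo=timezone.utc), p,
                           italian_utc_offset_minutes(t.date()))
        for t in t_el
    ])
    return (
        (float(tw.mean()), float(tw.std(ddof=1))),
        (float(has.mean()), float(has.std(ddof=1))),
    )


def _ou_positions(rng, n, sd_km, phi=0.85):
    dx = _ar1(rng, n, phi, sd_km)
    dy = _ar1(rng, n, phi, sd_km)
    return dx, dy


def simulate_tracks(
    config: SimConfig,
    grids: dict,
    birds: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """2-h fix streams for every bird plus the TruthRecord.

    Residents perform bounded correlated random walks around the colony.
    Migrants wait at the colony; each eligible nightly 2-h step departs with
    the configured logistic hazard evaluated on colony weather; flight steps
    head to the drawn destination at a speed driven by sex, segment tailwind
    and cumulative distance; arrival starts a >= 20-day dwell."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    t0 = pd.Timestamp(config.window_start, tz="UTC")
    t_end = pd.Timestamp(config.fixes_end, tz="UTC")
    fix_times = pd.date_range(t0, t_end, freq=f"{config.fix_interval_h}h")
    weather_end = pd.Timestamp(config.weather_end, tz="UTC")
    force_after = pd.Timestamp(config.force_departure_after, tz="UTC")

    colonies = {c.colony_id: c for c in config.colonies}
    eligible = _eligible_mask(fix_times)

    # per (colony, destination-bearing) standardization moments are expensive;
    # use per-colony moments for the modal destination bearing
    moments = {}
    for c in config.colonies:
        modal = max(c.destinations, key=lambda d: d.prob)
        moments[c.colony_id] = _colony_window_moments(
            config, c, modal.bearing_deg, grids, fix_times
        )

    tracks = []
    truth_birds = {}
    for _, bird in birds.iterrows():
        col = colonies[bird["colony"]]
        colony_pt = GeoPoint(col.lat, col.lon)
        dlat, dlon = _km_to_deg(col.lat)
        n = len(fix_times)
        if bird["migrate"] == 0:
            dx, dy = _ou_positions(rng, n, config.resident_sd_km)
            lats = col.lat + dy * dlat
            lons = col.lon + dx * dlon
            fixes = [
                Fix(bird["bird_id"], t.to_pydatetime(), GeoPoint(la, lo))
                for t, la, lo in zip(fix_times, lats, lons)
            ]
            tracks.append(Track(bird["bird_id"], col.colony_id, config.year, fixes))
            truth_birds[bird["bird_id"]] = {"strategy": "resident"}
            continue

        # destination draw
        probs = np.array([d.prob for d in col.destinations])
        dest = col.destinations[rng.choice(len(probs), p=probs / probs.sum())]
        dest_pt = destination_point(colony_pt, dest.bearing_deg, dest.distance_km)
        route_bearing = initial_bearing_deg(colony_pt, dest_pt)

        # readiness: colony phenology offset + sex offset + individual noise
        ready_days = (
            col.readiness_offset_days
            + (config.sex_readiness_offset_f_days if bird["sex"] == "F" else 0.0)
            + rng.normal(0.0, config.readiness_sd_days)
        )
        ready_t = t0 + pd.Timedelta(days=max(ready_days, 0.0))

        (tw_mu, tw_sd), (has_mu, has_sd) = moments[col.colony_id]

        # vectorized hazard over eligible steps after readiness
        cand_idx = np.nonzero(
            eligible & (fix_times >= ready_t) & (fix_times <= weather_end - pd.Timedelta(hours=6))
        )[0]
        cand_times = fix_times[cand_idx]
        tq = cand_times.tz_localize(None).values.astype("datetime64[ns]")
        u = interpolate_at(grids["wind_u"], np.full(len(tq), col.lat), np.full(len(tq), col.lon), tq)
        v = interpolate_at(grids["wind_v"], np.full(len(tq), col.lat), np.full(len(tq), col.lon), tq)
        spd, wdir = wind_speed_dir(u, v)
        tw = tailwind_kmh(spd, np.where(np.isfinite(wdir), wdir, 0.0), route_bearing)
        has = np.array([
            hours_after_sunset(t.to_pydatetime(), colony_pt,
                               italian_utc_offset_minutes(t.date()))
            for t in cand_times
        ])
        z_tw = (tw - tw_mu) / tw_sd
        z_h = (has - has_mu) / has_sd
        p_dep = expit(
            config.hazard_intercept
            + config.hazard_tailwind * z_tw
            + config.hazard_hours_after_sunset * z_h
            + config.hazard_hours_after_sunset_sq * z_h ** 2
        )
        draws = rng.random(len(p_dep))
        hits = np.nonzero(draws < p_dep)[0]
        if len(hits) and cand_times[hits[0]] <= force_after:
            k, forced = hits[0], False
        else:
            # hazard never fired in time: force departure at the first
            # eligible step past the cutoff so the event finishes by Nov 1
            late = np.nonzero(cand_times > force_after)[0]
            k, forced = (late[0] if len(late) else len(cand_times) - 1), True
        # the hazard step IS the first in-flight fix: the bird took off
        # between the previous fix and this one, so the label-1 covariates of
        # the case-control design coincide with the generative hazard inputs
        departure_idx = cand_idx[k]

        # build the fix stream: colony jitter before the departure fix,
        # flight from the departure fix on, then dwell at the destination
        b_bird = rng.normal(0.0, config.speed_bird_sd)
        pre_n = departure_idx
        dx, dy = _ou_positions(rng, pre_n, config.colony_radius_jitter_km)
        lats = list(col.lat + dy * dlat)
        lons = list(col.lon + dx * dlon)

        # stopover plan
        do_stop = (
            dest.distance_km > config.stopover_min_total_km
            and rng.random() < config.stopover_prob
        )
        stop_at_km = 0.55 * dest.distance_km
        stop_steps = int(np.ceil(config.stopover_dwell_h / config.fix_interval_h))

        cur = GeoPoint(col.lat, col.lon)
        cum = 0.0
        i = departure_idx
        seg_speeds = []
        arrival_idx = None
        stop_entry = None
        stopped = 0
        while i < n:
            t_i = fix_times[i]
            # the first flight fix covers ~1 h of flight (takeoff midway
            # through the preceding interval); later steps a full interval
            step_h = config.fix_interval_h / 2.0 if i == departure_idx else float(config.fix_interval_h)
            remaining = great_circle_km(cur, dest_pt)
            if remaining < 1e-6:
                arrival_idx = i
                break
            if do_stop and stop_entry is None and cum >= stop_at_km:
                stop_entry = i
            if stop_entry is not None and stopped < stop_steps:
                # stationary dwell en route
                lats.append(cur.lat_deg + rng.normal(0, 0.2) / 111.0)
                lons.append(cur.lon_deg + rng.normal(0, 0.2) / 111.0)
                stopped += 1
                i += 1
                continue
            brg = initial_bearing_deg(cur, dest_pt)
            t_np = np.datetime64(t_i.tz_localize(None), "ns")
            if t_i <= weather_end:
                uu = interpolate_at(grids["wind_u"], cur.lat_deg, cur.lon_deg, t_np)
                vv = interpolate_at(grids["wind_v"], cur.lat_deg, cur.lon_deg, t_np)
                sspd, sdir = wind_speed_dir(uu, vv)
                tw_i = tailwind_kmh(sspd, sdir if np.isfinite(sdir) else 0.0, brg)
            else:
                tw_i = tw_mu
            z_tw_i = (tw_i - tw_mu) / tw_sd
            z_d = (cum - config.cumdist_std_mean_km) / config.cumdist_std_sd_km
            speed = (
                config.speed_intercept_kmh
                + (config.speed_sex_m if bird["sex"] == "M" else 0.0)
                + config.speed_tailwind * z_tw_i
                + config.speed_cumdist * z_d
                + config.speed_cumdist_sq * z_d ** 2
                + b_bird
                + rng.normal(0.0, config.speed_resid_sd)
            )
            speed = max(25.0, float(speed))
            step_km = speed * step_h
            if step_km >= remaining:
                cur = dest_pt
                cum += remaining
                seg_speeds.append(remaining / step_h)
                lats.append(cur.lat_deg)
                lons.append(cur.lon_deg)
                arrival_idx = i
                i += 1
                break
            cur = destination_point(cur, brg, step_km)
            cum += step_km
            seg_speeds.append(speed)
            lats.append(cur.lat_deg)
            lons.append(cur.lon_deg)
            i += 1

        if arrival_idx is None:
            arrival_idx = n - 1
        # post-arrival dwell at the destination until data end
        n_post = n - len(lats)
        if n_post > 0:
            ddlat, ddlon = _km_to_deg(dest_pt.lat_deg)
            dx, dy = _ou_positions(rng, n_post, 1.2)
            lats.extend(dest_pt.lat_deg + dy * ddlat)
            lons.extend(dest_pt.lon_deg + dx * ddlon)

        fixes = [
            Fix(bird["bird_id"], t.to_pydatetime(), GeoPoint(la, lo))
            for t, la, lo in zip(fix_times, lats, lons)
        ]
        tracks.append(Track(bird["bird_id"], col.colony_id, config.year, fixes))
        dep_time = fix_times[departure_idx]  # first in-flight location
        arr_time = fix_times[arrival_idx]
        off = italian_utc_offset_minutes(arr_time.date())
        arr_local = (arr_time + pd.Timedelta(minutes=off)).date()
        strategy = "migrant" if arr_local < date(config.year, 11, 1) else "resident"
        truth_birds[bird["bird_id"]] = {
            "strategy": strategy,
            "departure_utc": dep_time.isoformat(),
            "arrival_utc": arr_time.isoformat(),
            "destination": dest.name,
            "destination_lat": dest_pt.lat_deg,
            "destination_lon": dest_pt.lon_deg,
            "route_bearing_deg": route_bearing,
            "route_distance_km": dest.distance_km,
            "segment_speeds_kmh": [float(s) for s in seg_speeds],
            "had_stopover": bool(do_stop and stop_entry is not None),
            "forced_departure": bool(forced),
        }

    truth = TruthRecord(
        birds=truth_birds,
        coefficients={
            "propensity": [config.propensity_intercept, config.propensity_slope],
            "hazard": [
                config.hazard_intercept, config.hazard_tailwind,
                config.hazard_hours_after_sunset, config.hazard_hours_after_sunset_sq,
            ],
            "speed": [
                config.speed_intercept_kmh, config.speed_sex_m, config.speed_tailwind,
                config.speed_cumdist, config.speed_cumdist_sq,
            ],
        },
        seed=config.seed,
    )
    return tracks, truth


def simulate_dataset(config: SimConfig):
    """One-call generation of (weather grids, birds, tracks, truth)."""
    ss = np.random.SeedSequence(config.seed).spawn(3)
    grids = simulate_weather(config, np.random.default_rng(ss[0]))
    birds = simulate_birds(config, np.random.default_rng(ss[1]))
    tracks, truth = simulate_tracks(config, grids, birds, np.random.default_rng(ss[2]))
    return grids, birds, tracks, truth


# ---------------------------------------------------------------------------
# Fixture bundle I/O
# ---------------------------------------------------------------------------

def write_fixture_set(config, grids, birds, tracks, truth, path, overwrite: bool = False):
    """Write the Movebank-style fixes CSV, weather NetCDF files, biometrics
    CSV, config YAML and truth JSON; reload is lossless."""
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    path.mkdir(parents=True, exist_ok=True)
    write_movebank_csv(tracks, path / "fixes.csv")
    atmos = {k: g for k, g in grids.items() if not k.startswith("cloud")}
    clouds = {k: g for k, g in grids.items() if k.startswith("cloud")}
    write_netcdf(atmos, path / "weather.nc")
    write_netcdf(clouds, path / "clouds.nc")
    birds.to_csv(path / "biometrics.csv", index=False)
    truth.to_json(path / "truth.json")
    config.to_yaml(path / "config.yaml")


def read_fixture_set(path):
    from .track_segment import read_movebank_csv
    from .weather_field import read_netcdf

    path = Path(path)
    config = SimConfig.from_yaml(path / "config.yaml")
    birds = pd.read_csv(path / "biometrics.csv")
    colony_ids = dict(zip(birds["bird_id"], birds["colony"]))
    hatch = dict(zip(birds["bird_id"], birds["year"]))
    tracks = read_movebank_csv(path / "fixes.csv", colony_ids, hatch)
    grids = {**read_netcdf(path / "weather.nc"), **read_netcdf(path / "clouds.nc")}
    truth = TruthRecord.from_json(path / "truth.json")
    return config, grids, birds, tracks, truth
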