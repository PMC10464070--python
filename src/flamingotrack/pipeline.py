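"""File-based pipeline stages: simulate -> segment -> annotate -> fit -> report.

Every stage reads its inputs from, and writes its outputs to, a single run
directory, so each stage is independently testable and a re-run with the
same seed and configuration reproduces identical result tables:

    run/
      data/     fixture bundle (fixes, weather, biometrics, truth, config)
      tables/   tidy CSV outputs of every analysis
      manifest.json
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circular_stats import (
    bin_directions,
    fit_direction_wind_glm,
    rayleigh_test,
    seasonal_wind_frequencies,
)
from .condition import add_smi, fit_biometric_models, fit_propensity
from .geo_solar import GeoPoint
from .study_models import (
    build_departure_cases,
    build_distance_table,
    build_phenology_table,
    build_speed_table,
    fit_departure_distance_interaction,
    fit_departure_model,
    fit_distance_model,
    fit_phenology_models,
    fit_speed_model,
)
from .synthetic_data import (
    SimConfig,
    read_fixture_set,
    simulate_dataset,
    write_fixture_set,
)
from .track_segment import classify_strategy, events_to_frame, extract_event

log = logging.getLogger("flamingotrack")

STAGES = ("simulate", "segment", "annotate", "fit", "report")


class MissingInputError(FileNotFoundError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fit_to_csv(fit, path: Path) -> None:
    tidy = fit.tidy()
    tt = fit.term_table.set_index("term") if not fit.term_table.empty else None
    if tt is not None:
        tidy = tidy.merge(
            tt.reset_index()[["term"] + [c for c in ("statistic", "df", "p") if c in tt.columns]],
            how="left", on="term",
        )
    tidy.to_csv(path, index=False, float_format="%.6g")


def stage_simulate(config: SimConfig, outdir: Path, overwrite: bool = False) -> Path:
    data_dir = Path(outdir) / "data"
    log.info("simulating dataset (seed=%s)", config.seed)
    grids, birds, tracks, truth = simulate_dataset(config)
    write_fixture_set(config, grids, birds, tracks, truth, data_dir, overwrite=overwrite)
    return data_dir


def _load(outdir: Path):
    data_dir = Path(outdir) / "data"
    if not (data_dir / "fixes.csv").exists():
        raise MissingInputError(
            f"no fixture bundle under {data_dir}; run the simulate stage first"
        )
    return read_fixture_set(data_dir)


def _events(config, tracks, colonies):
    """Classify every track; extract events for the migrants."""
    strategies = {}
    events = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr in tracks:
            colony = colonies[tr.colony_id]
            s = classify_strategy(tr, colony)
            strategies[tr.bird_id] = s
            if s == "migrant":
                events[tr.bird_id] = extract_event(tr, colony)
    return strategies, events


def stage_segment(outdir: Path) -> pd.DataFrame:
    config, grids, birds, tracks, truth = _load(outdir)
    colonies = {c.colony_id: GeoPoint(c.lat, c.lon) for c in config.colonies}
    strategies, events = _events(config, tracks, colonies)
    tables = Path(outdir) / "tables"
    tables.mkdir(exist_ok=True)
    strat = pd.DataFrame(
        {"bird_id": list(strategies), "strategy": list(strategies.values())}
    ).sort_values("bird_id")
    strat.to_csv(tables / "strategies.csv", index=False)
    ev = events_to_frame(events.values()).sort_values("bird_id")
    ev.to_csv(tables / "events.csv", index=False, float_format="%.6g")
    log.info("segmented %d tracks: %d migrants", len(tracks), len(events))
    return ev


def stage_annotate(outdir: Path) -> dict:
    config, grids, birds, tracks, truth = _load(outdir)
    colonies = {c.colony_id: GeoPoint(c.lat, c.lon) for c in config.colonies}
    strategies, events = _events(config, tracks, colonies)
    tracks_by_id = {t.bird_id: t for t in tracks}
    tables = Path(outdir) / "tables"
    tables.mkdir(exist_ok=True)

    cc = build_departure_cases(events, tracks_by_id, grids, colonies, birds)
    cc.table.to_csv(tables / "departure_cases.csv", index=False, float_format="%.8g")
    speed = build_speed_table(events, tracks_by_id, grids, birds)
    speed.to_csv(tables / "speed_segments.csv", index=False, float_format="%.8g")
    phen = build_phenology_table(events, tracks_by_id, birds)
    phen.to_csv(tables / "phenology.csv", index=False, float_format="%.8g")
    dist = build_distance_table(events, tracks_by_id, grids, birds)
    dist.to_csv(tables / "distance.csv", index=False, float_format="%.8g")
    log.info(
        "annotated: %d case-control rows (%d dropped), %d speed segments",
        len(cc.table), cc.n_dropped_missing_weather, len(speed),
    )
    return {"cases": cc.table, "speed": speed, "phenology": phen, "distance": dist}


def stage_fit(outdir: Path) -> dict:
    config, grids, birds, tracks, truth = _load(outdir)
    colonies = {c.colony_id: GeoPoint(c.lat, c.lon) for c in config.colonies}
    strategies, events = _events(config, tracks, colonies)
    tables = Path(outdir) / "tables"
    for name in ("departure_cases", "speed_segments", "phenology", "distance"):
        if not (tables / f"{name}.csv").exists():
            raise MissingInputError(f"{name}.csv missing; run the annotate stage first")
    cases = pd.read_csv(tables / "departure_cases.csv", parse_dates=["t_utc"])
    cases["year"] = cases["year"].astype(str)
    speed = pd.read_csv(tables / "speed_segments.csv", parse_dates=["t_utc"])
    speed["year"] = speed["year"].astype(str)
    phen = pd.read_csv(tables / "phenology.csv")
    phen["year"] = phen["year"].astype(str)
    dist = pd.read_csv(tables / "distance.csv")

    results = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # condition / propensity
        strat_df = pd.DataFrame(
            {"bird_id": list(strategies), "migrate": [int(s == "migrant") for s in strategies.values()]}
        )
        # observed strategy, not the generator's latent decision
        prop_table = add_smi(birds.drop(columns=["migrate"], errors="ignore")).merge(
            strat_df, on="bird_id"
        )
        results["propensity"] = fit_propensity(prop_table)
        for name, fit in fit_biometric_models(birds).items():
            results[f"biometrics_{name}"] = fit

        # departure GLMM and the tailwind x distance variant
        results["departure"] = fit_departure_model(cases)
        results["departure_interaction"] = fit_departure_distance_interaction(cases)

        # speed LMM and the sex x tailwind variant
        results["speed"] = fit_speed_model(speed)
        results["speed_sex_tailwind"] = fit_speed_model(speed, sex_tailwind_interaction=True)

        # phenology and distance LMs
        for name, fit in fit_phenology_models(phen).items():
            results[f"phenology_{name}"] = fit
        results["distance"] = fit_distance_model(dist)

    for name, fit in results.items():
        _fit_to_csv(fit, tables / f"fit_{name}.csv")

    # direction vs seasonal winds, per colony
    dep_times = [ev.departure_fix.t_utc for ev in events.values()]
    t_first, t_last = min(dep_times), max(dep_times)
    tracks_by_id = {t.bird_id: t for t in tracks}
    rows = []
    for col in config.colonies:
        bearings = [
            ev.destination_bearing_deg
            for bid, ev in events.items()
            if tracks_by_id[bid].colony_id == col.colony_id
        ]
        if len(bearings) < 1:
            continue
        wind_bins = seasonal_wind_frequencies(
            grids["wind_u"], grids["wind_v"], col.lat, col.lon, t_first, t_last
        )
        dep_bins = bin_directions(bearings)
        glm = fit_direction_wind_glm(dep_bins, wind_bins)
        slope = glm.params.get("wind_freq", np.nan)
        p = glm.term_table.set_index("term")["p"].get("wind_freq", np.nan)
        ray = rayleigh_test(bearings) if len(bearings) >= 3 else None
        rows.append(
            {
                "colony": col.colony_id,
                "n_migrants": int(dep_bins.total),
                "wind_bins": json.dumps(list(wind_bins.counts)),
                "departure_bins": json.dumps(list(dep_bins.counts)),
                "poisson_slope": slope,
                "poisson_p": p,
                "dispersion": glm.dispersion,
                "rayleigh_r": ray.mean_resultant_length if ray else np.nan,
                "rayleigh_p": ray.p_value if ray else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(tables / "direction_wind.csv", index=False, float_format="%.6g")
    log.info("fitted %d models", len(results) + len(rows))
    return results


def stage_report(outdir: Path) -> dict:
    """Assemble the run manifest and the headline summary."""
    outdir = Path(outdir)
    tables = outdir / "tables"
    data_dir = outdir / "data"
    if not tables.exists():
        raise MissingInputError("no tables/ to report on; run earlier stages first")
    config = SimConfig.from_yaml(data_dir / "config.yaml")

    headline = {}
    dep = pd.read_csv(tables / "fit_departure.csv").set_index("term")
    headline["departure_tailwind_estimate"] = float(dep.loc["tailwind", "estimate"])
    headline["departure_tailwind_positive"] = bool(dep.loc["tailwind", "ci_low"] > 0)
    spd = pd.read_csv(tables / "fit_speed.csv").set_index("term")
    headline["speed_sex_m_estimate"] = float(spd.loc["sex[M]", "estimate"])
    headline["speed_cumdist_sq_estimate"] = float(spd.loc["cumulative_km^2", "estimate"])
    headline["speed_profile_concave"] = bool(spd.loc["cumulative_km^2", "ci_high"] < 0)
    ev = pd.read_csv(tables / "events.csv")
    headline["n_migrants"] = int(len(ev))
    headline["mean_speed_kmh"] = float(ev["mean_speed_kmh"].mean())
    headline["mean_distance_km"] = float(ev["total_distance_km"].mean())

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _sha256(data_dir / "config.yaml"),
        "input_sha256": {
            p.name: _sha256(p) for p in sorted(data_dir.glob("*")) if p.is_file()
        },
        "tables_sha256": {
            p.name: _sha256(p) for p in sorted(tables.glob("*.csv"))
        },
        "row_counts": {
            p.name: sum(1 for _ in open(p)) - 1 for p in sorted(tables.glob("*.csv"))
        },
        "headline": headline,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run(stage: str, config: SimConfig, outdir, overwrite: bool = False):
    """Run one stage or `all`; stages communicate only through files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage not in STAGES + ("all",):
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    if stage in ("simulate", "all"):
        stage_simulate(config, outdir, overwrite=overwrite)
    if stage in ("segment", "all"):
        stage_segment(outdir)
    if stage in ("annotate", "all"):
        stage_annotate(outdir)
    if stage in ("fit", "all"):
        stage_fit(outdir)
    if stage in ("report", "all"):
        return stage_report(outdir)
    return None
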