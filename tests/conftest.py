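"""Shared fixtures: scaled-down simulation scenarios and tiny weather grids.

The scaled scenarios keep the full three-colony structure of the default
stated world but shorten the season so end-to-end tests stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from flamingotrack.synthetic_data import SimConfig, simulate_dataset
from flamingotrack.weather_field import WeatherGrid


def scaled_config(seed: int = 0, **overrides) -> SimConfig:
    """Default world with a shortened season (Aug 1 - mid Sep departures)."""
    kwargs = dict(
        seed=seed,
        window_start="2015-08-01",
        weather_end="2015-09-25",
        fixes_end="2015-10-20",
        force_departure_after="2015-09-05",
    )
    kwargs.update(overrides)
    cfg = SimConfig(**kwargs)
    for c in cfg.colonies:
        # compress colony phenology offsets into the shorter season
        c.readiness_offset_days = min(c.readiness_offset_days, 15.0)
    return cfg


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return scaled_config(seed=20150801)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(grids, birds, tracks, truth) for the scaled default scenario."""
    return simulate_dataset(small_config)


def linear_grid(variable="temperature", a=2.0, b=3.0, c=0.1):
    """Small grid whose field is linear in lat, lon and time (hours)."""
    times = np.arange(
        np.datetime64("2015-08-01"), np.datetime64("2015-08-03"), np.timedelta64(1, "h")
    )
    lats = np.arange(38.0, 40.01, 0.25)
    lons = np.arange(8.0, 10.01, 0.25)
    t_idx, la, lo = np.meshgrid(np.arange(len(times)), lats, lons, indexing="ij")
    return WeatherGrid(variable, times, lats, lons, a * la + b * lo + c * t_idx)


@pytest.fixture()
def lin_grid():
    return linear_grid()
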