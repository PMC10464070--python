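"""Circular statistics for departure directions and seasonal winds.

The seasonal-wind analysis asks whether the compass distribution of
departure bearings at a colony tracks the distribution of wind directions
over the migration season.  Because both distributions can be multimodal,
directions are discretised into six half-open 60-degree classes
([0,60), [60,120), ..., [300,360)) and the per-class departure counts are
regressed on the per-class wind frequencies with a Poisson GLM.

Uniformity of a direction sample is tested with the Rayleigh test:
mean resultant length r = |sum exp(i*theta)| / n, Z = n * r^2, with the
standard series approximation for the p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference_core import Cont, FitResult, ModelSpec, fit_glm
from .weather_field import WeatherGrid, interpolate_at, wind_speed_dir

N_BINS = 6
BIN_WIDTH_DEG = 360.0 // N_BINS


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class RayleighResult:
    n: int
    mean_resultant_length: float  # r in [0, 1]
    mean_direction_deg: float
    statistic: float  # Z = n * r^2
    p_value: float


def rayleigh_test(angles_deg) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    Returns the mean resultant length r (the 't' often quoted with this
    test), the mean direction, Z = n r^2 and the series-approximate p-value.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    n = a.size
    if n < 3:
        raise InsufficientDataError("Rayleigh test needs n >= 3 angles")
    C = float(np.cos(a).sum())
    S = float(np.sin(a).sum())
    R = np.hypot(C, S)
    r = R / n
    Z = n * r * r
    # Zar (1999) approximation
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - R * R)) - (1.0 + 2.0 * n))
    mean_dir = np.degrees(np.arctan2(S, C)) % 360.0
    return RayleighResult(n, r, mean_dir, Z, float(min(1.0, max(0.0, p))))


@dataclass(frozen=True)
class DirectionBins:
    """Counts of directions in six half-open 60-degree classes."""

    counts: tuple

    def __post_init__(self):
        if len(self.counts) != N_BINS:
            raise ValueError(f"expected {N_BINS} bin counts")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def as_series(self) -> pd.Series:
        labels = [
            f"[{int(i * BIN_WIDTH_DEG)},{int((i + 1) * BIN_WIDTH_DEG)})"
            for i in range(N_BINS)
        ]
        return pd.Series(self.counts, index=labels, name="count")


def bin_directions(angles_deg) -> DirectionBins:
    """Assign angles (normalized into [0, 360)) to the six 60-degree classes."""
    a = np.asarray(angles_deg, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    a = np.mod(a, 360.0)
    idx = np.floor(a / BIN_WIDTH_DEG).astype(int)
    idx = np.clip(idx, 0, N_BINS - 1)
    counts = np.bincount(idx, minlength=N_BINS)
    return DirectionBins(tuple(int(c) for c in counts))


def seasonal_wind_frequencies(
    u_grid: WeatherGrid,
    v_grid: WeatherGrid,
    colony_lat: float,
    colony_lon: float,
    start,
    end,
    step_h: int = 2,
) -> DirectionBins:
    """Wind blowing-toward directions sampled at the colony every step_h hours
    over [start, end] (the first-to-last departure period), binned into the
    six classes.  Calm samples (zero speed, undefined direction) are dropped."""
    t0 = np.datetime64(pd.Timestamp(start).to_datetime64(), "ns")
    t1 = np.datetime64(pd.Timestamp(end).to_datetime64(), "ns")
    if t1 < t0:
        raise ValueError("end precedes start")
    times = np.arange(t0, t1 + np.timedelta64(1, "ns"), np.timedelta64(step_h, "h"))
    lats = np.full(times.shape, colony_lat)
    lons = np.full(times.shape, colony_lon)
    u = interpolate_at(u_grid, lats, lons, times)
    v = interpolate_at(v_grid, lats, lons, times)
    speed, direction = wind_speed_dir(u, v)
    ok = np.isfinite(direction)
    return bin_directions(direction[ok])


def fit_direction_wind_glm(
    departure_bins: DirectionBins, wind_bins: DirectionBins
) -> FitResult:
    """Poisson GLM of per-class departure counts on per-class wind frequencies.

    Returns the fit with slope, Wald p and the Pearson dispersion statistic.
    With six observations per colony the inference is fragile; results are
    reported exactly, the small-n caveat is documented, never 'corrected'.
    """
    if departure_bins.total == 0:
        raise ValueError("degenerate fit: no departures in any class")
    df = pd.DataFrame(
        {
            "departures": list(departure_bins.counts),
            "wind_freq": list(wind_bins.counts),
        }
    )
    spec = ModelSpec("departures", [Cont("wind_freq")], family="poisson")
    return fit_glm(spec, df)
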