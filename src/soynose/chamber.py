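"""Chamber environment and session bookkeeping.

The plant grows inside an instrumented acrylic chamber whose internal
temperature, relative humidity and CO2 concentration are logged every five
minutes alongside external conditions and natural luminosity.  Gas samples
are drawn twice daily — morning (09:00-10:00) and afternoon (15:30-16:30)
local time — from day-after-sowing (DAS) 11 through 32, with irrigation
stopped after DAS 20.  This module provides the deterministic labelling of
sessions, empty-chamber baseline QC, summary statistics, per-period trend
lines, and the soil water-status helpers (gravimetric moisture on a
dry-mass basis, bulk density).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .acquisition import SensorTrace

DAS_MIN = 11
DAS_MAX = 32
LAST_IRRIGATED_DAS = 20

PERIODS = ("morning", "afternoon")
IRRIGATION_CLASSES = ("irrigated", "non_irrigated")

#: half-open local-time sampling windows [start, end)
MORNING_WINDOW = (_dt.time(9, 0), _dt.time(10, 0))
AFTERNOON_WINDOW = (_dt.time(15, 30), _dt.time(16, 30))

ENV_SAMPLE_CADENCE_MIN = 5


@dataclass(frozen=True)
class EnvSample:
    """One 5-minute chamber log record."""

    timestamp: _dt.datetime
    temp_int_c: float
    temp_ext_c: float
    rh_int_pct: float
    rh_ext_pct: float
    co2_int_ppm: float
    co2_ext_ppm: float
    lux_ext: float

    def __post_init__(self) -> None:
        for name in ("rh_int_pct", "rh_ext_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        for name in ("co2_int_ppm", "co2_ext_ppm", "lux_ext"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SessionRecord:
    """One (plant, DAS, period) sampling event.

    ``env`` is the aggregate chamber snapshot over the sampling window
    (keys ``temp_int_c``, ``rh_int_pct``, ``co2_int_ppm``, ``lux_ext`` at
    minimum); ``traces`` maps 1-based sensor index to the replicate
    acquisitions (n=3 injections per session by default).
    """

    plant: int
    das: int
    period: str
    irrigation: str
    env: dict[str, float]
    traces: dict[int, list[SensorTrace]] = field(default_factory=dict)
    date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not DAS_MIN <= self.das <= DAS_MAX:
            raise ValueError(f"das={self.das} outside experiment window [{DAS_MIN}, {DAS_MAX}]")
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}")
        expected = "irrigated" if self.das <= LAST_IRRIGATED_DAS else "non_irrigated"
        if self.irrigation != expected:
            raise ValueError(
                f"irrigation={self.irrigation!r} inconsistent with das={self.das} "
                f"(expected {expected!r})"
            )


def _parse_clock(clock: str | _dt.time | _dt.datetime) -> _dt.time:
    if isinstance(clock, _dt.datetime):
        return clock.time()
    if isinstance(clock, _dt.time):
        return clock
    hh, mm = str(clock).split(":")[:2]
    return _dt.time(int(hh), int(mm))


def label_session(das: int, clock: str | _dt.time | _dt.datetime) -> tuple[str, str]:
    """Deterministic (period, irrigation) labels for a sampling event.

    ``das`` must lie in the experiment window and ``clock`` inside one of
    the two half-open daylight sampling windows.
    """
    das = int(das)
    if not DAS_MIN <= das <= DAS_MAX:
        raise ValueError(f"das={das} outside experiment window [{DAS_MIN}, {DAS_MAX}]")
    t = _parse_clock(clock)
    if MORNING_WINDOW[0] <= t < MORNING_WINDOW[1]:
        period = "morning"
    elif AFTERNOON_WINDOW[0] <= t < AFTERNOON_WINDOW[1]:
        period = "afternoon"
    else:
        raise ValueError(f"clock {t} outside both sampling windows "
                         f"{MORNING_WINDOW[0]}-{MORNING_WINDOW[1]} and "
                         f"{AFTERNOON_WINDOW[0]}-{AFTERNOON_WINDOW[1]}")
    irrigation = "irrigated" if das <= LAST_IRRIGATED_DAS else "non_irrigated"
    return period, irrigation


class QCRange(NamedTuple):
    min: float
    max: float
    range: float


def baseline_qc(
    env: pd.DataFrame | Mapping[str, Sequence[float]],
) -> dict[str, QCRange]:
    """Per-variable (min, max, range) over an empty-chamber baseline period.

    Accepts the environmental frame or any mapping of variable name to a
    numeric series; non-numeric columns (timestamps, ids) are skipped.
    """
    if isinstance(env, pd.DataFrame):
        items = {
            c: env[c].to_numpy()
            for c in env.columns
            if pd.api.types.is_numeric_dtype(env[c])
        }
    else:
        items = {k: np.asarray(v, dtype=float) for k, v in env.items()}
    if not items or any(len(v) == 0 for v in items.values()):
        raise ValueError("baseline series must be non-empty")
    out: dict[str, QCRange] = {}
    for name, arr in items.items():
        lo, hi = float(np.min(arr)), float(np.max(arr))
        out[name] = QCRange(lo, hi, hi - lo)
    return out


class SummaryStats(NamedTuple):
    mean: float
    sd: float
    cv_pct: float
    n: int


def cv_pct(mean: float, sd: float) -> float:
    """Coefficient of variation (%) from a mean and standard deviation."""
    if mean == 0:
        raise ValueError("cv undefined for zero mean")
    return 100.0 * sd / mean


def summary_stats(series: Sequence[float]) -> SummaryStats:
    """Mean, sample SD (n-1), CV (%) and n of a series (n >= 2)."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1))
    cv = 0.0 if sd == 0.0 else cv_pct(mean, sd)
    return SummaryStats(mean, sd, cv, int(arr.size))


def linear_trend(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """OLS (slope, intercept) of value vs DAS, as drawn on the per-period trend lines."""
    pts = [(float(d), float(v)) for d, v in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("all DAS identical; trend undefined")
    fit = _stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept)


def gravimetric_moisture(wet_g: float, dry_g: float) -> float:
    """Gravimetric soil moisture theta_w (%) on a dry-mass basis.

    theta_w = 100 * (wet - dry) / dry.  Report to 1 decimal place.
    """
    if dry_g <= 0:
        raise ValueError("dry mass must be positive")
    if wet_g < dry_g:
        raise ValueError("wet mass cannot be below dry mass")
    return 100.0 * (wet_g - dry_g) / dry_g


def bulk_density(mass_g: float, volume_cm3: float) -> float:
    """Soil bulk density (g/cm^3).  Report to 2 decimal places."""
    if mass_g <= 0 or volume_cm3 <= 0:
        raise ValueError("mass and volume must be positive")
    return mass_g / volume_cm3


@dataclass(frozen=True)
class SoilSpec:
    """The dystrophic Red-Yellow Latosol used in the reference experiment."""

    clay_g_kg: float = 369.0
    silt_g_kg: float = 54.0
    sand_g_kg: float = 577.0
    field_capacity_cm3_cm3: float = 0.295
    wilting_point_cm3_cm3: float = 0.134
    dry_mass_g: float = 4758.0
    dry_volume_cm3: float = 8090.0

    def __post_init__(self) -> None:
        total = self.clay_g_kg + self.silt_g_kg + self.sand_g_kg
        if abs(total - 1000.0) > 50.0:
            raise ValueError(f"granulometry fractions sum to {total} g/kg, expected ~1000")
        if not 0.0 < self.wilting_point_cm3_cm3 < self.field_capacity_cm3_cm3 < 1.0:
            raise ValueError("need 0 < wilting point < field capacity < 1")

    @property
    def bulk_density_g_cm3(self) -> float:
        return bulk_density(self.dry_mass_g, self.dry_volume_cm3)


def window_bounds(period: str) -> tuple[_dt.time, _dt.time]:
    if period == "morning":
        return MORNING_WINDOW
    if period == "afternoon":
        return AFTERNOON_WINDOW
    raise ValueError(f"period must be one of {PERIODS}")


def session_env_snapshot(env: pd.DataFrame, day: _dt.date, period: str) -> dict[str, float]:
    """Mean of the 5-minute samples inside one day's sampling window.

    ``env`` needs a ``timestamp`` column (ISO-8601 or datetime) plus the
    numeric environment columns; returns their window means.
    """
    ts = pd.to_datetime(env["timestamp"])
    start, end = window_bounds(period)
    lo = _dt.datetime.combine(day, start)
    hi = _dt.datetime.combine(day, end)
    mask = (ts >= lo) & (ts < hi)
    if not mask.any():
        raise ValueError(f"no environmental samples for {day} {period} window")
    sub = env.loc[mask]
    return {
        c: float(sub[c].mean())
        for c in sub.columns
        if c != "timestamp" and pd.api.types.is_numeric_dtype(sub[c])
    }
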