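"""Radar-area statistic and classifier feature assembly.

The six per-sensor peak sensitivities of one gas sample are summarised by
the area of the radar (spider) polygon whose i-th vertex sits at radius
x_i on one of n equally spaced spokes:

    A_n = 1/2 * sin(2*pi/n) * sum_{i=1..n} x_{i-1} * x_i,   x_0 := x_n,

i.e. the shoelace area of the closed polygon.  The statistic needs n >= 3
axes.  Areas are computed on peak magnitudes |S| so that mixed-sign sensor
responses cannot produce a negative area; the signed peaks are kept as
separate features.

Feature vectors for the water-stress classifiers combine, per session
(one plant, one day-after-sowing, one daylight period):

* the six replicate-averaged signed peak sensitivities,
* the radar area of their magnitudes,
* the chamber environment snapshot (internal T/RH/CO2, external lux),
* trailing-window OLS slopes of each |peak| and of internal temperature
  across days, within the same daylight period (the "regression" features
  named in the published decision tree).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .acquisition import (
    SENSOR_LABELS,
    compute_sensitivity,
    estimate_baseline,
    peak_sensitivity,
)

N_SENSORS = len(SENSOR_LABELS)

PEAK_COLUMNS = [f"peak_s{i}" for i in range(1, N_SENSORS + 1)]
ENV_COLUMNS = ["temp_int", "rh_int", "co2_int", "lux_ext"]
REG_COLUMNS = [f"reg_max_s{i}" for i in range(1, N_SENSORS + 1)]
FEATURE_COLUMNS = PEAK_COLUMNS + ["radar_area"] + ENV_COLUMNS + REG_COLUMNS + ["reg_temp_int"]
TABLE_COLUMNS = ["plant", "das", "period"] + FEATURE_COLUMNS + ["label"]

#: session env-snapshot key -> feature column
_ENV_KEY_MAP = {
    "temp_int_c": "temp_int",
    "rh_int_pct": "rh_int",
    "co2_int_ppm": "co2_int",
    "lux_ext": "lux_ext",
}


def radar_area(values: Sequence[float]) -> float:
    """Area (in units of value^2) of the radar polygon over ``values``.

    ``values`` are taken in spoke order with cyclic closure; n >= 3 axes
    are required for the polygon to exist.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size < 3:
        raise ValueError(f"radar chart needs at least 3 axes, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = x.size
    return float(0.5 * math.sin(2.0 * math.pi / n) * np.dot(x, np.roll(x, 1)))


def trend_feature(
    points: Sequence[tuple[float, float]],
    window: int | None = 5,
    standardize: bool = False,
) -> float:
    """OLS slope of value versus day over the trailing ``window`` points.

    ``points`` are (day, value) pairs; they are sorted by day and the last
    ``window`` (all of them if ``window`` is None) are fitted.  At least two
    points with distinct days are required.

    With ``standardize=True`` the slope is scaled by sqrt(Sxx), the square
    root of the window's design variance ``sum((day - mean day)^2)``.  The
    OLS slope of iid noise has variance sigma^2/Sxx, so the scaled value
    has a sampling variance independent of how many days the window holds
    — early sessions (short windows) and late ones become comparable, and
    the feature cannot encode elapsed time through its own noise level.
    """
    if window is not None and window < 2:
        raise ValueError("window must be >= 2")
    pts = sorted((float(d), float(v)) for d, v in points)
    if window is not None:
        pts = pts[-window:]
    if len(pts) < 2:
        raise ValueError("need at least 2 points for a trend")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("all days identical; slope undefined")
    slope = float(_stats.linregress(x, y).slope)
    if standardize:
        sxx = float(np.sum((x - x.mean()) ** 2))
        slope *= math.sqrt(sxx)
    return slope


@dataclass
class NormalizationStats:
    """Per-feature min/max fitted on training data, for [0,1] scaling."""

    mins: pd.Series
    maxs: pd.Series

    def __post_init__(self) -> None:
        if not self.mins.index.equals(self.maxs.index):
            raise ValueError("mins and maxs must share an index")
        if bool((self.maxs < self.mins).any()):
            raise ValueError("max < min for some feature")

    @classmethod
    def fit(cls, frame: pd.DataFrame, columns: Sequence[str] | None = None) -> "NormalizationStats":
        cols = list(columns) if columns is not None else list(frame.columns)
        sub = frame[cols].astype(float)
        return cls(sub.min(axis=0), sub.max(axis=0))

    def transform_value(self, name: str, value: float) -> float:
        lo, hi = float(self.mins[name]), float(self.maxs[name])
        if hi == lo:  # degenerate feature carries no information
            return 0.0
        return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))

    def transform_frame(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for name in self.mins.index:
            lo, hi = float(self.mins[name]), float(self.maxs[name])
            if hi == lo:
                out[name] = 0.0
            else:
                out[name] = ((frame[name] - lo) / (hi - lo)).clip(0.0, 1.0)
        return out

    @classmethod
    def identity(cls, columns: Sequence[str]) -> "NormalizationStats":
        idx = pd.Index(columns)
        return cls(pd.Series(0.0, index=idx), pd.Series(1.0, index=idx))


@dataclass
class FeatureVector:
    """Classifier input for one (plant, DAS, period) session."""

    plant: int
    das: int
    period: str
    label: str
    per_sensor_peak: dict[int, float]
    peak_sd: dict[int, float]
    radar_area_pct2: float
    env: dict[str, float]
    trend: dict[str, float] = field(default_factory=dict)
    normalized: bool = False

    def as_row(self) -> dict[str, float | int | str]:
        row: dict[str, float | int | str] = {
            "plant": self.plant,
            "das": self.das,
            "period": self.period,
        }
        for i in range(1, N_SENSORS + 1):
            row[f"peak_s{i}"] = self.per_sensor_peak[i]
        row["radar_area"] = self.radar_area_pct2
        for key, col in _ENV_KEY_MAP.items():
            row[col] = self.env[key]
        for col in REG_COLUMNS + ["reg_temp_int"]:
            row[col] = self.trend.get(col, math.nan)
        row["label"] = self.label
        return row


def build_feature_vector(
    session,
    history: Sequence[FeatureVector] = (),
    *,
    trend_window: int | None = 5,
    baseline_policy: str = "mean-first-k",
) -> FeatureVector:
    """Assemble one session's feature vector.

    ``session`` is a :class:`soynose.chamber.SessionRecord`; ``history``
    holds feature vectors of earlier sessions of the same plant (other
    plants/periods are filtered out here).  Trend features need at least
    two points in the window and are NaN ("absent") otherwise — in
    particular for the first session of each daylight period.
    """
    peaks: dict[int, float] = {}
    sds: dict[int, float] = {}
    for idx in range(1, N_SENSORS + 1):
        traces = session.traces.get(idx)
        if not traces:
            raise ValueError(f"session {session.plant}/{session.das}/{session.period} "
                             f"is missing sensor S{idx} ({SENSOR_LABELS[idx - 1]})")
        reps = []
        for tr in traces:
            r0 = estimate_baseline(tr, policy=baseline_policy)
            reps.append(peak_sensitivity(compute_sensitivity(tr, r0)))
        peaks[idx] = float(np.mean(reps))
        sds[idx] = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0

    area = radar_area([abs(peaks[i]) for i in range(1, N_SENSORS + 1)])
    env = {key: float(session.env[key]) for key in _ENV_KEY_MAP}

    prior = [fv for fv in history if fv.plant == session.plant and fv.period == session.period]
    trend: dict[str, float] = {}
    for i in range(1, N_SENSORS + 1):
        pts = [(fv.das, abs(fv.per_sensor_peak[i])) for fv in prior]
        pts.append((session.das, abs(peaks[i])))
        trend[f"reg_max_s{i}"] = (
            trend_feature(pts, window=trend_window, standardize=True)
            if len(pts) >= 2 else math.nan
        )
    tpts = [(fv.das, fv.env["temp_int_c"]) for fv in prior]
    tpts.append((session.das, env["temp_int_c"]))
    trend["reg_temp_int"] = (
        trend_feature(tpts, window=trend_window, standardize=True)
        if len(tpts) >= 2 else math.nan
    )

    return FeatureVector(
        plant=session.plant,
        das=session.das,
        period=session.period,
        label=session.irrigation,
        per_sensor_peak=peaks,
        peak_sd=sds,
        radar_area_pct2=area,
        env=env,
        trend=trend,
    )


_PERIOD_ORDER = {"morning": 0, "afternoon": 1}


def build_feature_table(
    sessions: Iterable,
    *,
    trend_window: int | None = 5,
    baseline_policy: str = "mean-first-k",
) -> tuple[pd.DataFrame, list[FeatureVector]]:
    """Feature table (one row per plant/DAS/period) from session records.

    Sessions are processed in chronological order per plant so that trend
    features only ever look backwards.
    """
    ordered = sorted(sessions, key=lambda s: (s.plant, s.das, _PERIOD_ORDER[s.period]))
    history: dict[int, list[FeatureVector]] = {}
    vectors: list[FeatureVector] = []
    for session in ordered:
        fv = build_feature_vector(
            session,
            history.get(session.plant, ()),
            trend_window=trend_window,
            baseline_policy=baseline_policy,
        )
        history.setdefault(session.plant, []).append(fv)
        vectors.append(fv)
    table = pd.DataFrame([fv.as_row() for fv in vectors], columns=TABLE_COLUMNS)
    return table, vectors
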