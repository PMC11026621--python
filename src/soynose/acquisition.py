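"""E-nose acquisition traces and resistance-based sensitivity curves.

The instrument records, for each of six n-type tin-oxide (MOS) sensors, the
electrical resistance R(t) at 1 Hz over a 240 s acquisition while a 500 µl
headspace sample is carried over the sensor array.  A sensor's response is
summarised by its sensitivity relative to the pre-exposure baseline R0,

    S(%) = 100 * (R - R0) / R0,

so a negative S means the sensor became more conductive (the usual MOS
response to reducing gases).  The peak of |S| per sensor is the scalar
feature that feeds the radar-area statistic and the classifiers.

The instrument reports R0 implicitly; this module estimates it from the
opening samples of the trace (mean of the first five by default, which is
robust to single-sample noise), with a ``first-sample`` policy as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Fixed sensor order S1..S6 of the six-element array.
SENSOR_LABELS: tuple[str, ...] = ("T30/1", "P10/1", "P10/2", "P40/1", "T70/2", "PA/2")

BASELINE_POLICIES = ("mean-first-k", "first-sample")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Instrument settings for one acquisition cycle.

    ``duration_s`` bounds the recorded trace; ``total_time_s`` is the full
    acquisition-cycle length including the purge and is metadata only.
    The sensor chamber is held at 64 degC and 0 % RH so ambient humidity
    does not modulate the MOS response during a reading.
    """

    duration_s: int = 240
    period_s: float = 1.0
    total_time_s: int = 300
    flow_ml_min: float = 150.0
    injection_volume_ul: float = 500.0
    injection_speed_ul_s: float = 500.0
    internal_temp_c: float = 64.0
    internal_rh_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.total_time_s <= 0:
            raise ValueError("durations must be positive")
        if self.duration_s > self.total_time_s:
            raise ValueError("duration_s cannot exceed total_time_s")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        for name in ("flow_ml_min", "injection_volume_ul", "injection_speed_ul_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.internal_rh_pct < 0:
            raise ValueError("internal_rh_pct must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s / self.period_s))

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.period_s


@dataclass(frozen=True, order=True)
class SensorId:
    """One of the six array sensors, identified by its catalogue label."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in SENSOR_LABELS:
            raise ValueError(f"unknown sensor label {self.label!r}; expected one of {SENSOR_LABELS}")

    @property
    def index(self) -> int:
        """1-based position S1..S6 in the fixed array order."""
        return SENSOR_LABELS.index(self.label) + 1

    @property
    def short(self) -> str:
        return f"S{self.index}"

    @classmethod
    def from_index(cls, index: int) -> "SensorId":
        if not 1 <= index <= len(SENSOR_LABELS):
            raise ValueError(f"sensor index must be in 1..{len(SENSOR_LABELS)}, got {index}")
        return cls(SENSOR_LABELS[index - 1])


def _as_series(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class SensorTrace:
    """One sensor's resistance time series for one acquisition."""

    sensor: SensorId
    times_s: np.ndarray
    resistance_ohm: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = _as_series(self.times_s, "times_s")
        self.resistance_ohm = _as_series(self.resistance_ohm, "resistance_ohm")
        if self.times_s.shape != self.resistance_ohm.shape:
            raise ValueError("times_s and resistance_ohm must have the same length")
        if abs(self.times_s[0]) > 1e-9:
            raise ValueError("trace must start at t=0")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        if np.any(self.resistance_ohm <= 0):
            raise ValueError("resistance must be positive everywhere")

    def __len__(self) -> int:
        return self.times_s.size


def check_uniform_sampling(trace: SensorTrace, period_s: float = 1.0, rtol: float = 0.1) -> None:
    """Reject traces with dropped samples.

    Acquisition is short (240 s at 1 Hz), so gaps are treated as corrupt
    input rather than interpolated.
    """
    if len(trace) < 2:
        return
    dt = np.diff(trace.times_s)
    if np.any(np.abs(dt - period_s) > rtol * period_s):
        bad = int(np.argmax(np.abs(dt - period_s) > rtol * period_s))
        raise ValueError(
            f"trace for {trace.sensor.label} has a sampling gap near t={trace.times_s[bad]:.1f}s "
            f"(dt={dt[bad]:.3f}s, expected {period_s}s)"
        )


@dataclass
class SensitivityCurve:
    """Baseline-relative response S(%) of one sensor over one acquisition."""

    sensor: SensorId
    times_s: np.ndarray
    s_pct: np.ndarray
    r0_ohm: float

    def __post_init__(self) -> None:
        self.times_s = _as_series(self.times_s, "times_s")
        self.s_pct = _as_series(self.s_pct, "s_pct")
        if self.times_s.shape != self.s_pct.shape:
            raise ValueError("times_s and s_pct must have the same length")
        if self.r0_ohm <= 0:
            raise ValueError("r0_ohm must be positive")

    def __len__(self) -> int:
        return self.times_s.size


def estimate_baseline(trace: SensorTrace, policy: str = "mean-first-k", k: int = 5) -> float:
    """Estimate the pre-response baseline resistance R0 (ohm).

    ``mean-first-k`` (default) averages the first ``k`` samples;
    ``first-sample`` takes the opening sample verbatim.
    """
    if policy not in BASELINE_POLICIES:
        raise ValueError(f"unknown baseline policy {policy!r}; expected one of {BASELINE_POLICIES}")
    if policy == "first-sample":
        return float(trace.resistance_ohm[0])
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(np.mean(trace.resistance_ohm[: min(k, len(trace))]))


def compute_sensitivity(trace: SensorTrace, r0_ohm: float) -> SensitivityCurve:
    """Transform a resistance trace into a sensitivity curve S(%)."""
    if r0_ohm <= 0:
        raise ValueError("r0_ohm must be positive")
    s = 100.0 * (trace.resistance_ohm - r0_ohm) / r0_ohm
    return SensitivityCurve(trace.sensor, trace.times_s.copy(), s, float(r0_ohm))


def sensitivity_to_resistance(curve: SensitivityCurve) -> SensorTrace:
    """Invert a sensitivity curve back to the resistance trace, R = R0(1+S/100)."""
    r = curve.r0_ohm * (1.0 + curve.s_pct / 100.0)
    return SensorTrace(curve.sensor, curve.times_s.copy(), r)


def peak_sensitivity(curve: SensitivityCurve) -> float:
    """Signed sensitivity value of largest absolute magnitude.

    Ties in |S| are broken by earliest time.  For the usual reducing-gas
    response the result is negative (resistance drop); oxidising responses
    yield a positive peak.
    """
    idx = int(np.argmax(np.abs(curve.s_pct)))
    return float(curve.s_pct[idx])


# ---------------------------------------------------------------------------
# CSV interchange for a single acquisition


def read_acquisition_csv(path: str | Path) -> dict[str, SensorTrace]:
    """Read one acquisition (columns ``sensor,time_s,resistance_ohm``).

    Returns traces keyed by sensor label, each sorted by time.
    """
    df = pd.read_csv(path)
    required = {"sensor", "time_s", "resistance_ohm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces: dict[str, SensorTrace] = {}
    for label, grp in df.groupby("sensor", sort=False):
        grp = grp.sort_values("time_s")
        traces[str(label)] = SensorTrace(
            SensorId(str(label)),
            grp["time_s"].to_numpy(dtype=float),
            grp["resistance_ohm"].to_numpy(dtype=float),
        )
    return traces


def write_sensitivity_csv(
    curves: Mapping[str, SensitivityCurve] | Iterable[SensitivityCurve],
    path: str | Path,
) -> Path:
    """Write sensitivity curves plus a ``*_peaks.csv`` sidecar of R0 and peaks."""
    if isinstance(curves, Mapping):
        curve_list = list(curves.values())
    else:
        curve_list = list(curves)
    path = Path(path)
    frames = [
        pd.DataFrame(
            {"sensor": c.sensor.label, "time_s": c.times_s, "s_pct": c.s_pct}
        )
        for c in curve_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    sidecar = path.with_name(path.stem + "_peaks.csv")
    pd.DataFrame(
        {
            "sensor": [c.sensor.label for c in curve_list],
            "r0_ohm": [c.r0_ohm for c in curve_list],
            "peak_s_pct": [peak_sensitivity(c) for c in curve_list],
        }
    ).to_csv(sidecar, index=False)
    return sidecar
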