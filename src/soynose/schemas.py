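"""CSV schema validation for the pipeline's interchange tables."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .acquisition import SENSOR_LABELS
from .chamber import DAS_MAX, DAS_MIN, LAST_IRRIGATED_DAS, PERIODS
from .radar import TABLE_COLUMNS

SCHEMA_COLUMNS: dict[str, list[str]] = {
    "acquisitions": ["plant", "das", "period", "replicate", "sensor", "time_s", "resistance_ohm"],
    "environment": ["plant", "timestamp", "temp_int_c", "temp_ext_c", "rh_int_pct",
                    "rh_ext_pct", "co2_int_ppm", "co2_ext_ppm", "lux_ext"],
    "sessions": ["plant", "das", "date", "period", "irrigation"],
    "features": list(TABLE_COLUMNS),
}


def _check_numeric(df: pd.DataFrame, col: str, violations: list[str],
                   lo: float | None = None, hi: float | None = None,
                   strict_lo: bool = False) -> None:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    for i in df.index[bad][:5]:
        violations.append(f"column {col!r}, row {i}: non-numeric value {df[col][i]!r}")
    if lo is not None:
        mask = (vals <= lo) if strict_lo else (vals < lo)
        for i in df.index[mask.fillna(False)][:5]:
            cmp = "<=" if strict_lo else "<"
            violations.append(f"column {col!r}, row {i}: value {vals[i]} {cmp} {lo}")
    if hi is not None:
        for i in df.index[(vals > hi).fillna(False)][:5]:
            violations.append(f"column {col!r}, row {i}: value {vals[i]} > {hi}")


def validate_frame(df: pd.DataFrame, schema: str) -> list[str]:
    """Return violations (empty list means the frame conforms)."""
    if schema not in SCHEMA_COLUMNS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMA_COLUMNS)}")
    violations: list[str] = []
    required = SCHEMA_COLUMNS[schema]
    missing = [c for c in required if c not in df.columns]
    for c in missing:
        violations.append(f"missing column {c!r}")
    if missing:
        return violations

    if schema == "acquisitions":
        _check_numeric(df, "resistance_ohm", violations, lo=0.0, strict_lo=True)
        _check_numeric(df, "time_s", violations, lo=0.0)
        _check_numeric(df, "das", violations, lo=DAS_MIN, hi=DAS_MAX)
        bad = ~df["sensor"].isin(SENSOR_LABELS)
        for i in df.index[bad][:5]:
            violations.append(f"column 'sensor', row {i}: unknown sensor {df['sensor'][i]!r}")
        bad = ~df["period"].isin(PERIODS)
        for i in df.index[bad][:5]:
            violations.append(f"column 'period', row {i}: invalid period {df['period'][i]!r}")
    elif schema == "environment":
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
        for i in df.index[ts.isna()][:5]:
            violations.append(f"column 'timestamp', row {i}: unparseable timestamp "
                              f"{df['timestamp'][i]!r}")
        _check_numeric(df, "rh_int_pct", violations, lo=0.0, hi=100.0)
        _check_numeric(df, "rh_ext_pct", violations, lo=0.0, hi=100.0)
        _check_numeric(df, "co2_int_ppm", violations, lo=0.0)
        _check_numeric(df, "co2_ext_ppm", violations, lo=0.0)
        _check_numeric(df, "lux_ext", violations, lo=0.0)
    elif schema == "sessions":
        _check_numeric(df, "das", violations, lo=DAS_MIN, hi=DAS_MAX)
        bad = ~df["period"].isin(PERIODS)
        for i in df.index[bad][:5]:
            violations.append(f"column 'period', row {i}: invalid period {df['period'][i]!r}")
        das = pd.to_numeric(df["das"], errors="coerce")
        expected = np.where(das <= LAST_IRRIGATED_DAS, "irrigated", "non_irrigated")
        bad = df["irrigation"].to_numpy() != expected
        for i in df.index[bad & das.notna()][:5]:
            violations.append(
                f"column 'irrigation', row {i}: {df['irrigation'][i]!r} inconsistent "
                f"with das={df['das'][i]}"
            )
    elif schema == "features":
        _check_numeric(df, "das", violations, lo=DAS_MIN, hi=DAS_MAX)
        _check_numeric(df, "radar_area", violations, lo=0.0)
        bad = ~df["period"].isin(PERIODS)
        for i in df.index[bad][:5]:
            violations.append(f"column 'period', row {i}: invalid period {df['period'][i]!r}")
    return violations


def validate_input(path: str | Path, schema: str) -> list[str]:
    """Validate a CSV file against a named schema; returns violations."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable / malformed file
        return [f"unreadable CSV: {exc}"]
    return validate_frame(df, schema)
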