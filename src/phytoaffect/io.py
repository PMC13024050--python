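"""CSV trace I/O and flat YAML configuration files.

Traces travel as tidy UTF-8 CSV with a fixed header per kind
(environment: ``timestamp,temperature,humidity,light,infrared,heater,fan``;
plant: ``timestamp,bioelectric,eco2,tvoc``), comma-separated with '.'
decimals.  Timestamps may be epoch seconds or ISO-8601; they must be
strictly increasing, and gaps larger than twice the nominal period are
logged.
"""

from __future__ import annotations

import logging
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .synthetic import ChamberConfig, CouplingConfig, EnvironmentTrace, PlantTrace

__all__ = [
    "ENV_COLUMNS",
    "PLANT_COLUMNS",
    "write_trace_csv",
    "read_trace_csv",
    "load_config",
    "save_config",
]

log = logging.getLogger(__name__)

ENV_COLUMNS = ["timestamp", "temperature", "humidity", "light", "infrared", "heater", "fan"]
PLANT_COLUMNS = ["timestamp", "bioelectric", "eco2", "tvoc"]

_EPOCH = pd.Timestamp("1970-01-01", tz="UTC")


def write_trace_csv(
    trace: EnvironmentTrace | PlantTrace,
    path: str | Path,
    timestamp_format: str = "epoch",
) -> None:
    """Write a trace as tidy CSV (epoch-seconds or ISO-8601 timestamps)."""
    df = trace.to_frame()
    if timestamp_format == "iso":
        df["timestamp"] = (
            _EPOCH + pd.to_timedelta(df["timestamp"], unit="s")
        ).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    elif timestamp_format != "epoch":
        raise DataError("timestamp_format must be 'epoch' or 'iso'")
    df.to_csv(path, index=False)


def _parse_timestamps(col: pd.Series, path: str | Path) -> np.ndarray:
    try:
        return col.astype(float).to_numpy()
    except (ValueError, TypeError):
        pass
    try:
        parsed = pd.to_datetime(col, utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise DataError(f"{path}: timestamps are neither numeric nor ISO-8601: {exc}")
    return (parsed - _EPOCH).dt.total_seconds().to_numpy()


def read_trace_csv(path: str | Path, kind: str) -> EnvironmentTrace | PlantTrace:
    """Load a trace CSV of the given kind ('environment' or 'plant')."""
    expected = {"environment": ENV_COLUMNS, "plant": PLANT_COLUMNS}.get(kind)
    if expected is None:
        raise DataError("kind must be 'environment' or 'plant'")
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"{path}: malformed CSV: {exc}")
    if list(df.columns) != expected:
        raise DataError(
            f"{path}: header {list(df.columns)} does not match schema {expected}"
        )
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise DataError(f"{path}: malformed row at line {bad[0] + 2}")

    ts = _parse_timestamps(df["timestamp"], path)
    dts = np.diff(ts)
    if len(ts) < 2 or (dts <= 0).any():
        where = int(np.argmax(dts <= 0)) + 2 if len(ts) >= 2 else 0
        raise DataError(f"{path}: timestamps not strictly increasing (near line {where})")
    nominal = float(np.median(dts))
    n_gaps = int((dts > 2.0 * nominal).sum())
    if n_gaps:
        log.warning(
            "%s: %d gaps exceed 2x the nominal period (%.3g s)", path, n_gaps, nominal
        )

    if kind == "environment":
        return EnvironmentTrace(
            timestamps=ts,
            temperature=df["temperature"].to_numpy(float),
            humidity=df["humidity"].to_numpy(float),
            light=df["light"].to_numpy(float),
            infrared=df["infrared"].to_numpy(float),
            heater_state=df["heater"].to_numpy(int),
            fan_state=df["fan"].to_numpy(int),
        )
    return PlantTrace(
        timestamps=ts,
        bioelectric=df["bioelectric"].to_numpy(float),
        eco2=df["eco2"].to_numpy(float),
        tvoc=df["tvoc"].to_numpy(float),
    )


def _from_flat(cls, mapping: dict):
    names = {f.name for f in dc_fields(cls)}
    kwargs = {k: v for k, v in mapping.items() if k in names}
    return cls(**kwargs)


def load_config(path: str | Path) -> dict:
    """Load a flat YAML key-value file into typed config objects.

    Recognised top-level sections: ``chamber``, ``coupling`` (others are
    passed through untouched so pipeline-level settings live alongside).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise DataError(f"{path}: config must be a mapping")
    out = dict(raw)
    if "chamber" in raw:
        out["chamber"] = _from_flat(ChamberConfig, raw["chamber"])
    if "coupling" in raw:
        out["coupling"] = _from_flat(CouplingConfig, raw["coupling"])
    return out


def save_config(config: dict, path: str | Path) -> None:
    from dataclasses import asdict, is_dataclass

    flat = {
        k: (asdict(v) if is_dataclass(v) else v) for k, v in config.items()
    }
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=False))
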