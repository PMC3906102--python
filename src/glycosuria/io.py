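"""File formats: `time_min,value` CSV time series and flat JSON parameters."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError
from .glycemia import TimeSeries


def read_timeseries(path, kind: str = "glycemia") -> TimeSeries:
    """Read a `time_min,value` CSV ('.' decimal, UTF-8)."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_min", "value"]:
        raise ValidationError(
            f"{path}: expected header 'time_min,value', got {list(df.columns)}")
    return TimeSeries(times=df["time_min"].to_numpy(dtype=float),
                      values=df["value"].to_numpy(dtype=float), kind=kind)


def write_timeseries(path, series: TimeSeries) -> None:
    pd.DataFrame({"time_min": series.times, "value": series.values}).to_csv(
        path, index=False)


def read_params(path) -> dict:
    """Flat JSON object keyed by parameter symbol names."""
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict):
        raise ValidationError(f"{path}: expected a flat JSON object")
    return obj


def write_params(path, params: dict) -> None:
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
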