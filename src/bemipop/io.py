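"""CSV readers/writers for the package's file dialects.

Dialects (headers are fixed):
  temperature:     date,tmean_c
  monitoring:      date,stage,count
  stage series:    date,day_index,egg,nymph,pupa,adult_repro,adult_post,adult_total
  DE trace:        generation,best_rss
  backcast trace:  date,tmean_c,stage,rate,remaining_age

Dates are ISO-8601 throughout.  Readers validate eagerly and report row
numbers in errors; every writer's output round-trips through the matching
reader.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .backcast import BackcastResult
from .cohorts import STAGE_NAMES, StageSeries
from .fitting import FitResult
from .timeseries import MonitoringSeries, TemperatureSeries


def _read_csv(path, required_columns) -> pd.DataFrame:
    try:
        # round_trip: parsed floats reproduce the written values exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise FileNotFoundError(f"input file not found: {path}") from None
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def _parse_dates(df: pd.DataFrame, path) -> pd.DatetimeIndex:
    try:
        return pd.DatetimeIndex(pd.to_datetime(df["date"], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable date ({exc})") from None


def read_temperature(path) -> TemperatureSeries:
    """Read a daily temperature CSV; gaps and non-numeric cells are errors."""
    df = _read_csv(path, ("date", "tmean_c"))
    dates = _parse_dates(df, path)
    temps = pd.to_numeric(df["tmean_c"], errors="coerce").to_numpy(float)
    bad = np.nonzero(~np.isfinite(temps))[0]
    if len(bad):
        # +2: one for the header line, one for 0-based indexing
        raise ValueError(f"{path}: non-numeric temperature at row(s) "
                         f"{[int(i) + 2 for i in bad]}")
    return TemperatureSeries(dates, temps)


def write_temperature(series: TemperatureSeries, path) -> None:
    df = series.to_frame()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_monitoring(path) -> MonitoringSeries:
    """Read a monitoring CSV (date,stage,count); unknown stages rejected."""
    df = _read_csv(path, ("date", "stage", "count"))
    dates = _parse_dates(df, path)
    counts = pd.to_numeric(df["count"], errors="coerce").to_numpy(float)
    bad = np.nonzero(~np.isfinite(counts))[0]
    if len(bad):
        raise ValueError(f"{path}: non-numeric count at row(s) "
                         f"{[int(i) + 2 for i in bad]}")
    return MonitoringSeries(pd.DataFrame(
        {"date": dates, "stage": df["stage"], "count": counts}))


def write_monitoring(series: MonitoringSeries, path) -> None:
    df = series.records.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def write_stage_series(series: StageSeries, path) -> None:
    df = series.to_frame()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_stage_series(path) -> StageSeries:
    df = _read_csv(path, ("date", "day_index") + STAGE_NAMES)
    dates = _parse_dates(df, path)
    table = df[list(STAGE_NAMES)].to_numpy(float)
    return StageSeries(dates=dates, table=table)


def write_de_trace(result: FitResult, path) -> None:
    pd.DataFrame({"generation": np.arange(1, len(result.trace) + 1),
                  "best_rss": result.trace}).to_csv(path, index=False)


def write_fit_result(result: FitResult, report_path, keyvalue_path) -> None:
    """Human-readable report plus machine-readable key=value file."""
    d = result.to_dict()
    with open(keyvalue_path, "w") as fh:
        for k, v in d.items():
            fh.write(f"{k}={v!r}\n")
    lines = [
        f"initial-condition fit ({result.mode})",
        f"  seed          {result.seed}",
        f"  generations   {result.generations} "
        f"({'converged' if result.converged else 'budget exhausted'})",
        f"  achieved RSS  {result.rss:.6g}",
        "  estimates:",
    ]
    for name in result.param_names:
        lines.append(f"    {name:<12} {d[name]:.6g}")
    with open(report_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_fit_keyvalues(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                k, v = line.split("=", 1)
                out[k] = float(v)
    return out


def write_backcast_trace(result: BackcastResult, path) -> None:
    df = result.trace.copy()
    if len(df):
        df["date"] = pd.DatetimeIndex(df["date"]).strftime("%Y-%m-%d")
    df.to_csv(path, index=False)
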