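"""Dated input series: daily temperatures and stage-specific monitoring counts.

Both containers validate on construction so that every downstream routine can
assume contiguous daily temperature coverage and non-negative counts on known
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: stages observable in the field (visual counts on plants)
OBSERVABLE_STAGES = ("adult", "nymph")


@dataclass(frozen=True)
class TemperatureSeries:
    """Contiguous daily mean-temperature record.

    Parameters
    ----------
    dates : pandas.DatetimeIndex
        Strictly increasing, gap-free daily dates.
    tmean : numpy.ndarray
        Mean daily temperature in °C, same length as ``dates``, all finite.
    """

    dates: pd.DatetimeIndex
    tmean: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates).normalize()
        tmean = np.asarray(self.tmean, dtype=float)
        if len(dates) != len(tmean):
            raise ValueError("dates and tmean must have equal length")
        if len(dates) == 0:
            raise ValueError("temperature series is empty")
        if not np.all(np.isfinite(tmean)):
            bad = dates[~np.isfinite(tmean)]
            raise ValueError(f"non-finite temperature at {list(bad.date)}")
        deltas = np.diff(dates.view("int64"))
        one_day = int(pd.Timedelta(days=1).value)
        if np.any(deltas != one_day):
            gaps = dates[:-1][deltas != one_day]
            missing = [str((g + pd.Timedelta(days=1)).date()) for g in gaps]
            raise ValueError(f"temperature series has gaps after: {missing}")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "tmean", tmean)

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def start(self) -> pd.Timestamp:
        return self.dates[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.dates[-1]

    def index_of(self, date) -> int:
        date = pd.Timestamp(date).normalize()
        i = (date - self.start) // pd.Timedelta(days=1)
        if i < 0 or i >= len(self):
            raise KeyError(f"date {date.date()} outside temperature series "
                           f"[{self.start.date()}, {self.end.date()}]")
        return int(i)

    def at(self, date) -> float:
        """Mean temperature (°C) on a calendar date."""
        return float(self.tmean[self.index_of(date)])

    def window(self, start, n_days: int) -> np.ndarray:
        """Temperatures for ``n_days`` consecutive days from ``start``."""
        i = self.index_of(start)
        if i + n_days > len(self):
            last_needed = pd.Timestamp(start) + pd.Timedelta(days=n_days - 1)
            raise KeyError(
                f"temperature series ends {self.end.date()}, before required "
                f"{last_needed.date()}")
        return self.tmean[i:i + n_days]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "tmean_c": self.tmean})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TemperatureSeries":
        return cls(pd.DatetimeIndex(df["date"]), df["tmean_c"].to_numpy(float))


@dataclass(frozen=True)
class MonitoringSeries:
    """Dated observed counts per observable stage (adult, nymph).

    ``records`` holds one row per field observation with columns
    ``date`` (Timestamp), ``stage`` (str) and ``count`` (float >= 0).
    ``n_obs`` is the number of records entering the fitting objective.
    """

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.records.copy()
        required = {"date", "stage", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"monitoring records need columns {sorted(required)}")
        if len(df) == 0:
            raise ValueError("monitoring series is empty")
        df["date"] = pd.DatetimeIndex(df["date"]).normalize()
        df["stage"] = df["stage"].astype(str)
        unknown = set(df["stage"]) - set(OBSERVABLE_STAGES)
        if unknown:
            raise ValueError(
                f"unknown stage label(s) {sorted(unknown)}; "
                f"observable stages are {OBSERVABLE_STAGES}")
        counts = df["count"].to_numpy(float)
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ValueError("counts must be finite and non-negative")
        df = df.sort_values(["date", "stage"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "records", df)

    @property
    def n_obs(self) -> int:
        return len(self.records)

    @property
    def first_date(self) -> pd.Timestamp:
        return self.records["date"].iloc[0]

    @property
    def last_date(self) -> pd.Timestamp:
        return self.records["date"].iloc[-1]

    def counts_for(self, stage: str) -> pd.DataFrame:
        return self.records[self.records["stage"] == stage]
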