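"""Calendar-indexed daily series.

The whole pipeline operates on contiguous civil-calendar daily series:
every calendar day between the first and last date is present exactly
once.  Temperatures may carry missing values (NaN); counts are complete
non-negative integers (a day with no recorded event is an explicit 0).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DailySeries", "stable_doy", "daily_index"]


def daily_index(start: str | pd.Timestamp, end: str | pd.Timestamp) -> pd.DatetimeIndex:
    """Contiguous daily DatetimeIndex from *start* to *end* inclusive."""
    return pd.date_range(start, end, freq="D")


def stable_doy(dates: pd.DatetimeIndex) -> np.ndarray:
    """Leap-stable day-of-year: Feb 29 is 60 and Mar 1 is 61 in every year.

    Ordinary ``dayofyear`` shifts Mar-Dec by one in leap years, which would
    smear climatologies across adjacent calendar days.  Values run 1..366;
    doy 60 only ever occurs in leap years.
    """
    doy = dates.dayofyear.to_numpy().copy()
    shift = (~dates.is_leap_year) & (dates.month.to_numpy() >= 3)
    doy[shift] += 1
    return doy


@dataclass(frozen=True)
class DailySeries:
    """One variable observed on a contiguous run of calendar days.

    Parameters
    ----------
    dates
        Strictly increasing, gap-free daily DatetimeIndex.
    values
        Float array aligned with ``dates``.  NaN marks a missing day
        (allowed only when ``kind != "count"``).
    kind
        ``"value"`` for real-valued variables (temperatures, anomalies),
        ``"count"`` for non-negative integer event counts.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    kind: str = "value"
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)
        if len(dates) != len(values):
            raise ValueError("dates and values must have equal length")
        if len(dates) == 0:
            raise ValueError("empty series")
        diffs = np.diff(dates.to_numpy().astype("datetime64[D]").view(np.int64))
        if np.any(diffs <= 0):
            raise ValueError("dates must be strictly increasing")
        if np.any(diffs != 1):
            missing = dates[:-1][diffs != 1][0] + pd.Timedelta(days=1)
            raise ValueError(f"calendar gap detected starting {missing.date()}")
        if self.kind == "count":
            if np.any(~np.isfinite(values)):
                raise ValueError("counts must be complete (no missing values)")
            if np.any(values < 0) or np.any(values != np.round(values)):
                raise ValueError("counts must be non-negative integers")
        else:
            if np.any(np.isinf(values)):
                raise ValueError("values must be finite or NaN")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def doy(self) -> np.ndarray:
        return stable_doy(self.dates)

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.dates, name=self.name or None)

    @classmethod
    def from_pandas(cls, s: pd.Series, kind: str = "value", name: str = "") -> "DailySeries":
        return cls(pd.DatetimeIndex(s.index), s.to_numpy(dtype=float), kind=kind,
                   name=name or (s.name or ""))

    def same_calendar(self, other: "DailySeries") -> bool:
        return len(self) == len(other) and bool((self.dates == other.dates).all())
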