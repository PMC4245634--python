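"""Reading and writing the standard daily CSV (date,tmax,tmin,count)."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .series import DailySeries

__all__ = ["DailyBundle", "read_daily_csv", "write_daily_csv"]

COLUMNS = ["date", "tmax", "tmin", "count"]


@dataclass(frozen=True)
class DailyBundle:
    """The three aligned daily series the pipeline consumes."""

    tmax: DailySeries
    tmin: DailySeries
    count: DailySeries

    def __post_init__(self) -> None:
        if not (self.tmax.same_calendar(self.tmin)
                and self.tmax.same_calendar(self.count)):
            raise ValueError("bundle series must share one calendar")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.tmax.dates

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates.strftime("%Y-%m-%d"),
                             "tmax": self.tmax.values,
                             "tmin": self.tmin.values,
                             "count": self.count.values.astype(int)})


def read_daily_csv(path: str | Path, absence_means_zero: bool = False) -> DailyBundle:
    """Parse the daily CSV, enforcing a contiguous calendar.

    Header must be exactly ``date,tmax,tmin,count`` with ISO-8601 dates.
    Calendar gaps are an error unless ``absence_means_zero`` is set, in
    which case missing days are filled with count 0 and missing
    temperatures.  Errors cite the offending 1-based file line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != COLUMNS:
        raise ValueError(f"{path}: header must be {','.join(COLUMNS)!r}, "
                         f"got {','.join(df.columns)!r}")

    def fail(i: int, msg: str) -> None:
        raise ValueError(f"{path}:{i + 2}: {msg}")  # +2: header + 1-based

    dates = []
    for i, raw in enumerate(df["date"]):
        try:
            dates.append(pd.Timestamp(f"{raw}"))
        except (ValueError, TypeError):
            fail(i, f"unparseable date {raw!r}")
    dates = pd.DatetimeIndex(dates)

    dup = pd.Series(dates).duplicated()
    if dup.any():
        fail(int(dup.idxmax()), f"duplicate date {dates[dup.idxmax()].date()}")
    if not dates.is_monotonic_increasing:
        bad = int(np.argmax(np.diff(dates.to_numpy()) < np.timedelta64(0)))
        fail(bad + 1, "dates are not in increasing order")

    def parse_col(col: str, required: bool) -> np.ndarray:
        out = np.empty(len(df))
        for i, raw in enumerate(df[col]):
            if raw.strip() == "":
                if required:
                    fail(i, f"missing {col} value")
                out[i] = np.nan
                continue
            try:
                out[i] = float(raw)
            except ValueError:
                fail(i, f"unparseable {col} value {raw!r}")
        return out

    tmax = parse_col("tmax", required=False)
    tmin = parse_col("tmin", required=False)
    count = parse_col("count", required=True)

    full = pd.date_range(dates[0], dates[-1], freq="D")
    if len(full) != len(dates):
        if not absence_means_zero:
            missing = full.difference(dates)[0]
            raise ValueError(f"{path}: calendar gap at {missing.date()} "
                             "(pass absence_means_zero to fill with count 0)")
        frame = pd.DataFrame({"tmax": tmax, "tmin": tmin, "count": count},
                             index=dates).reindex(full)
        frame["count"] = frame["count"].fillna(0.0)
        tmax, tmin, count = (frame[c].to_numpy() for c in ("tmax", "tmin", "count"))
        dates = full

    return DailyBundle(DailySeries(dates, tmax, name="tmax"),
                       DailySeries(dates, tmin, name="tmin"),
                       DailySeries(dates, count, kind="count", name="count"))


def write_daily_csv(bundle: DailyBundle | pd.DataFrame, path: str | Path) -> None:
    """Write the daily table (comma, dot-decimal, UTF-8, LF)."""
    frame = bundle.to_frame() if isinstance(bundle, DailyBundle) else bundle
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
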