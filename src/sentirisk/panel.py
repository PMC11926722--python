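"""Weekly region-level panel containers and their tidy-CSV I/O.

Two rectangular region x week panels flow through the analysis:

* :class:`ClimatePanel` — weekly temperature (deg C) and precipitation
  (nonnegative, in the covariate's native unit) per region;
* :class:`SentimentPanel` — weekly counts of negative documents ``ntw``
  (the Poisson response) and total documents ``ttw`` (the exposure).

Weeks are 7-day bins anchored at a configured origin date, not ISO
calendar weeks, so that event windows defined in days align exactly with
week boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
import datetime as dt

import numpy as np
import pandas as pd

__all__ = ["ClimatePanel", "SentimentPanel", "week_index"]

#: Default first day of the study window.
DEFAULT_WEEK_ORIGIN = dt.date(2019, 1, 1)


def week_index(ts, origin: dt.date) -> int:
    """7-day bin index of a date/datetime relative to ``origin``."""
    d = ts.date() if isinstance(ts, dt.datetime) else ts
    return (d - origin).days // 7


def _week_starts(origin: dt.date, n_weeks: int) -> list[dt.date]:
    return [origin + dt.timedelta(days=7 * t) for t in range(n_weeks)]


def _check_weeks(week_starts) -> list[dt.date]:
    ws = [w.date() if isinstance(w, dt.datetime) else w for w in week_starts]
    diffs = {(b - a).days for a, b in zip(ws, ws[1:])}
    if diffs - {7}:
        raise ValueError("week starts must increase strictly by 7 days")
    return ws


@dataclass(frozen=True)
class ClimatePanel:
    region_ids: tuple[str, ...]
    week_starts: tuple[dt.date, ...]
    temperature: np.ndarray  # (n_regions, n_weeks), deg C
    precipitation: np.ndarray  # (n_regions, n_weeks), >= 0

    def __post_init__(self):
        object.__setattr__(
            self, "week_starts", tuple(_check_weeks(self.week_starts))
        )
        shape = (len(self.region_ids), len(self.week_starts))
        for name in ("temperature", "precipitation"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing/non-finite cells")
            object.__setattr__(self, name, arr)
        if np.any(self.precipitation < 0):
            raise ValueError("precipitation must be nonnegative")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_weeks(self) -> int:
        return len(self.week_starts)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.region_ids):
            for t, w in enumerate(self.week_starts):
                rows.append(
                    (r, w.isoformat(), self.temperature[i, t],
                     self.precipitation[i, t])
                )
        return pd.DataFrame(
            rows,
            columns=["region", "week_start", "temperature", "precipitation"],
        )

    @classmethod
    def from_csv(cls, path) -> "ClimatePanel":
        df = pd.read_csv(path, dtype={"region": str})
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClimatePanel":
        regions = tuple(dict.fromkeys(df["region"]))
        weeks = sorted({dt.date.fromisoformat(str(w)[:10])
                        for w in df["week_start"]})
        ridx = {r: i for i, r in enumerate(regions)}
        widx = {w: t for t, w in enumerate(weeks)}
        temp = np.full((len(regions), len(weeks)), np.nan)
        prec = np.full((len(regions), len(weeks)), np.nan)
        for _, row in df.iterrows():
            i = ridx[row["region"]]
            t = widx[dt.date.fromisoformat(str(row["week_start"])[:10])]
            temp[i, t] = row["temperature"]
            prec[i, t] = row["precipitation"]
        return cls(regions, tuple(weeks), temp, prec)


@dataclass(frozen=True)
class SentimentPanel:
    """Weekly negative (``ntw``) and total (``ttw``) document counts."""

    region_ids: tuple[str, ...]
    week_starts: tuple[dt.date, ...]
    ntw: np.ndarray  # (n_regions, n_weeks) int
    ttw: np.ndarray  # (n_regions, n_weeks) int

    def __post_init__(self):
        object.__setattr__(
            self, "week_starts", tuple(_check_weeks(self.week_starts))
        )
        shape = (len(self.region_ids), len(self.week_starts))
        for name in ("ntw", "ttw"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError(f"{name} must be integer counts")
                arr = arr.astype(np.int64)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
            object.__setattr__(self, name, arr.astype(np.int64))
        if np.any(self.ntw > self.ttw):
            raise ValueError("ntw must not exceed ttw in any cell")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_weeks(self) -> int:
        return len(self.week_starts)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.region_ids):
            for t, w in enumerate(self.week_starts):
                rows.append(
                    (r, w.isoformat(), int(self.ntw[i, t]),
                     int(self.ttw[i, t]))
                )
        return pd.DataFrame(rows, columns=["region", "week_start", "ntw", "ttw"])

    @classmethod
    def from_csv(cls, path) -> "SentimentPanel":
        df = pd.read_csv(path, dtype={"region": str})
        regions = tuple(dict.fromkeys(df["region"]))
        weeks = sorted({dt.date.fromisoformat(str(w)[:10])
                        for w in df["week_start"]})
        ridx = {r: i for i, r in enumerate(regions)}
        widx = {w: t for t, w in enumerate(weeks)}
        ntw = np.zeros((len(regions), len(weeks)), np.int64)
        ttw = np.zeros((len(regions), len(weeks)), np.int64)
        for _, row in df.iterrows():
            i = ridx[row["region"]]
            t = widx[dt.date.fromisoformat(str(row["week_start"])[:10])]
            ntw[i, t] = row["ntw"]
            ttw[i, t] = row["ttw"]
        return cls(regions, tuple(weeks), ntw, ttw)
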