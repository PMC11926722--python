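"""Covariate categorization and flood event windows.

The model enters temperature and precipitation as ordered categories:
precipitation in three levels (low / mid / high with cuts 0.01 and
0.035 in the covariate's native unit) and temperature in four levels
(cuts 15, 19 and 23 deg C).  Intervals are left-closed/right-open, with
the first category unbounded below and the last unbounded above, so
every finite value falls in exactly one category.

The July 2021 German flood is bracketed by three contiguous 28-day
windows: before (2021-05-25..2021-06-21), during
(2021-06-22..2021-07-19) and after (2021-07-20..2021-08-16).
"""

from __future__ import annotations

from dataclasses import dataclass
import datetime as dt

import numpy as np
import pandas as pd

from .panel import ClimatePanel, week_index

__all__ = [
    "CategoryScheme",
    "EventWindows",
    "categorize",
    "assign_event_period",
    "weekly_regional_covariate",
    "TEMPERATURE_SCHEME",
    "PRECIPITATION_SCHEME",
    "FLOOD_WINDOWS",
]


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered categories from strictly increasing interior cut points."""

    breaks: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        b = tuple(float(x) for x in self.breaks)
        if any(x >= y for x, y in zip(b, b[1:])):
            raise ValueError("breaks must be strictly increasing")
        if len(self.labels) != len(b) + 1:
            raise ValueError("need exactly len(breaks)+1 labels")
        object.__setattr__(self, "breaks", b)

    @property
    def n_categories(self) -> int:
        return len(self.labels)


TEMPERATURE_SCHEME = CategoryScheme(
    breaks=(15.0, 19.0, 23.0), labels=("low", "mid", "average", "high")
)
PRECIPITATION_SCHEME = CategoryScheme(
    breaks=(0.01, 0.035), labels=("low", "mid", "high")
)


def categorize(value, scheme: CategoryScheme):
    """Category index (0-based) of ``value`` under ``scheme``.

    Left-closed/right-open: a value equal to a cut point belongs to the
    category above it.  Vectorized over array input.
    """
    arr = np.asarray(value, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot categorize non-finite values")
    idx = np.searchsorted(np.asarray(scheme.breaks), arr, side="right")
    return int(idx) if np.isscalar(value) or arr.ndim == 0 else idx


@dataclass(frozen=True)
class EventWindows:
    """Three contiguous 28-day windows bracketing an extreme event."""

    before: tuple[dt.date, dt.date]
    during: tuple[dt.date, dt.date]
    after: tuple[dt.date, dt.date]

    def __post_init__(self):
        prev_end = None
        for name in ("before", "during", "after"):
            start, end = getattr(self, name)
            if (end - start).days != 27:
                raise ValueError(f"{name} window must span exactly 28 days")
            if prev_end is not None and (start - prev_end).days != 1:
                raise ValueError("windows must be contiguous, non-overlapping")
            prev_end = end

    def week_indices(self, origin: dt.date, n_weeks: int) -> dict[str, list[int]]:
        """Model-week indices covered by each window (clipped to range)."""
        out: dict[str, list[int]] = {}
        for name in ("before", "during", "after"):
            start, end = getattr(self, name)
            lo, hi = week_index(start, origin), week_index(end, origin)
            out[name] = [t for t in range(lo, hi + 1) if 0 <= t < n_weeks]
        return out


FLOOD_WINDOWS = EventWindows(
    before=(dt.date(2021, 5, 25), dt.date(2021, 6, 21)),
    during=(dt.date(2021, 6, 22), dt.date(2021, 7, 19)),
    after=(dt.date(2021, 7, 20), dt.date(2021, 8, 16)),
)


def assign_event_period(d: dt.date, windows: EventWindows = FLOOD_WINDOWS) -> str:
    """Which window a date falls in: 'before', 'during', 'after' or 'none'.

    Membership is inclusive on both endpoints.
    """
    if isinstance(d, dt.datetime):
        d = d.date()
    for name in ("before", "during", "after"):
        start, end = getattr(windows, name)
        if start <= d <= end:
            return name
    return "none"


def weekly_regional_covariate(
    daily: pd.DataFrame,
    value_column: str,
    reducer: str = "mean",
    week_origin: dt.date | None = None,
) -> pd.DataFrame:
    """Reduce a per-region daily series to one value per region-week bin.

    ``daily`` needs columns ``region``, ``date`` and ``value_column``.
    Bins are the same 7-day bins used by panel aggregation.  Gaps in the
    daily series raise with the list of missing days, since a silent
    mean over a partial week would bias the covariate.
    """
    if reducer not in ("mean", "sum"):
        raise ValueError("reducer must be 'mean' or 'sum'")
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if week_origin is None:
        week_origin = min(df["date"])
    # completeness check per region over the covered span
    gaps = []
    for region, grp in df.groupby("region"):
        have = set(grp["date"])
        lo, hi = min(have), max(have)
        span = {lo + dt.timedelta(days=k) for k in range((hi - lo).days + 1)}
        gaps.extend((region, d) for d in sorted(span - have))
    if gaps:
        shown = ", ".join(f"{r}:{d}" for r, d in gaps[:10])
        raise ValueError(f"missing daily values ({len(gaps)} gaps): {shown}")
    df["week"] = [week_index(d, week_origin) for d in df["date"]]
    agg = (
        df.groupby(["region", "week"])[value_column]
        .agg(reducer)
        .reset_index()
        .rename(columns={value_column: "value"})
    )
    agg["week_start"] = [
        (week_origin + dt.timedelta(days=7 * int(w))).isoformat()
        for w in agg["week"]
    ]
    return agg[["region", "week", "week_start", "value"]]


def categorize_panel(
    climate: ClimatePanel,
    temp_scheme: CategoryScheme = TEMPERATURE_SCHEME,
    precip_scheme: CategoryScheme = PRECIPITATION_SCHEME,
) -> tuple[np.ndarray, np.ndarray]:
    """Category index arrays (region x week) for temperature/precipitation."""
    tcat = categorize(climate.temperature, temp_scheme)
    pcat = categorize(climate.precipitation, precip_scheme)
    return tcat, pcat
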