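"""Marine-heatwave detection from daily SST series.

A marine heatwave (MHW) is an anomalously warm event in which daily SST
exceeds the seasonally varying 90th-percentile climatological threshold for
at least five consecutive days; two events separated by fewer than three
sub-threshold days are merged into one.  The climatology (mean and
threshold) is computed per calendar day from an 11-day window pooled across
the climatological years and smoothed with a 31-day circular moving average.
Event intensities are measured **relative to the threshold** (daily SST
minus threshold SST); a flag switches to the more common
relative-to-climatological-mean convention for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SSTSeries",
    "Climatology",
    "MHWEvent",
    "SiteMHWSummary",
    "build_climatology",
    "detect_events",
    "aggregate_site_mhw",
    "read_sst_csv",
]


@dataclass
class SSTSeries:
    """Contiguous daily SST record; missing days as NaN."""

    dates: pd.DatetimeIndex
    sst: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.sst = np.asarray(self.sst, dtype=float)
        if len(self.dates) != len(self.sst):
            raise ValueError("dates and sst differ in length")
        step = np.diff(self.dates.values).astype("timedelta64[D]")
        if len(step) and not (step == np.timedelta64(1, "D")).all():
            raise ValueError("dates must be contiguous daily")

    def missing_fraction(self) -> float:
        return float(np.isnan(self.sst).mean())


def read_sst_csv(path, sep: str = ",") -> SSTSeries:
    """Read a two-column (date, sst) CSV into an SSTSeries."""
    df = pd.read_csv(path, sep=sep, parse_dates=["date"])
    df = df.set_index("date").asfreq("D")  # reindex to contiguous days
    return SSTSeries(df.index, df["sst"].to_numpy())


def day_of_year_366(dates: pd.DatetimeIndex) -> np.ndarray:
    """Calendar day on a fixed 366-day grid (Feb 29 = 60, Mar 1 = 61 always)."""
    doy = dates.dayofyear.to_numpy().copy()
    shift = (~dates.is_leap_year) & (dates.month >= 3)
    doy[shift] += 1
    return doy


@dataclass
class Climatology:
    """Per-calendar-day baseline mean and 90th-percentile threshold."""

    clim_mean: np.ndarray  # length 366, index = day-of-year - 1
    clim_threshold: np.ndarray  # length 366

    def mean_for(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return self.clim_mean[day_of_year_366(dates) - 1]

    def threshold_for(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return self.clim_threshold[day_of_year_366(dates) - 1]


def _circular_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over a circular array, skipping NaN slots."""
    if window <= 1:
        return x.copy()
    half = window // 2
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        idx = (np.arange(i - half, i + half + 1)) % n
        vals = x[idx]
        out[i] = np.nanmean(vals) if not np.all(np.isnan(vals)) else np.nan
    return out


def build_climatology(
    sst: SSTSeries,
    clim_start: int,
    clim_end: int,
    window_half_width: int = 5,
    smooth_window: int = 31,
    percentile: float = 90.0,
    max_missing: float = 0.10,
    allow_missing: bool = False,
) -> Climatology:
    """Seasonally varying climatological mean and percentile threshold.

    For each of the 366 calendar days, values within ``window_half_width``
    days of it (pooled across all years clim_start..clim_end) feed the mean
    and the ``percentile`` (linear-interpolation convention); both curves are
    then smoothed with a ``smooth_window``-day circular moving average.

    A series with more than ``max_missing`` missing data in the period is
    refused unless ``allow_missing``.  Periods shorter than 30 years are
    accepted with a warning.
    """
    in_period = (sst.dates.year >= clim_start) & (sst.dates.year <= clim_end)
    if not in_period.any():
        raise ValueError("no data in climatological period")
    vals = sst.sst[in_period]
    dates = sst.dates[in_period]
    miss = float(np.isnan(vals).mean())
    if miss > max_missing and not allow_missing:
        raise ValueError(
            f"{miss:.1%} of SST missing in climatological period exceeds the "
            f"{max_missing:.0%} limit (pass allow_missing=True to override)"
        )
    if clim_end - clim_start + 1 < 30:
        warnings.warn(
            "climatological period shorter than the recommended 30 years", stacklevel=2
        )
    doy = day_of_year_366(dates)
    by_day: list[np.ndarray] = [np.array([])] * 366
    order = np.argsort(doy)
    sorted_doy = doy[order]
    sorted_vals = vals[order]
    bounds = np.searchsorted(sorted_doy, np.arange(1, 368))
    for d in range(1, 367):
        by_day[d - 1] = sorted_vals[bounds[d - 1] : bounds[d]]

    mean = np.full(366, np.nan)
    thr = np.full(366, np.nan)
    for d in range(366):
        window_days = (np.arange(d - window_half_width, d + window_half_width + 1)) % 366
        pooled = np.concatenate([by_day[w] for w in window_days])
        pooled = pooled[~np.isnan(pooled)]
        if len(pooled) == 0:
            continue
        mean[d] = pooled.mean()
        thr[d] = np.percentile(pooled, percentile)
    return Climatology(
        _circular_moving_average(mean, smooth_window),
        _circular_moving_average(thr, smooth_window),
    )


@dataclass
class MHWEvent:
    """One (possibly merged) marine heatwave.

    Merged events include their sub-threshold gap days, so daily intensities
    can be non-positive on those days; duration counts every day from start
    to end inclusive.
    """

    start_date: pd.Timestamp
    end_date: pd.Timestamp
    duration: int
    mean_intensity: float
    max_intensity: float
    cumulative_intensity: float
    daily_dates: pd.DatetimeIndex = field(repr=False)
    daily_intensity: np.ndarray = field(repr=False)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def detect_events(
    sst: SSTSeries,
    clim: Climatology,
    min_duration: int = 5,
    max_gap: int = 2,
    relative_to: str = "threshold",
) -> list[MHWEvent]:
    """Detect marine heatwaves: runs of SST above the climatological threshold.

    Runs of at least ``min_duration`` consecutive above-threshold days become
    events; qualifying events separated by at most ``max_gap`` sub-threshold
    days are merged (including the gap days).  Missing SST days break runs.
    Intensities are SST minus the threshold (``relative_to="threshold"``, the
    default) or minus the climatological mean (``relative_to="mean"``).
    """
    thr = clim.threshold_for(sst.dates)
    baseline = thr if relative_to == "threshold" else clim.mean_for(sst.dates)
    if relative_to not in ("threshold", "mean"):
        raise ValueError("relative_to must be 'threshold' or 'mean'")
    above = np.where(np.isnan(sst.sst) | np.isnan(thr), False, sst.sst > thr)
    events = [r for r in _runs(above) if r[1] - r[0] + 1 >= min_duration]

    merged: list[tuple[int, int]] = []
    for r in events:
        if merged and r[0] - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)

    out = []
    for a, b in merged:
        dates = sst.dates[a : b + 1]
        intensity = sst.sst[a : b + 1] - baseline[a : b + 1]
        intensity = np.where(np.isnan(intensity), 0.0, intensity)  # gap-day safety
        out.append(
            MHWEvent(
                start_date=dates[0],
                end_date=dates[-1],
                duration=b - a + 1,
                mean_intensity=float(intensity.mean()),
                max_intensity=float(intensity.max()),
                cumulative_intensity=float(intensity.sum()),
                daily_dates=dates,
                daily_intensity=intensity,
            )
        )
    return out


@dataclass
class SiteMHWSummary:
    """MHW intensity metrics aggregated over the years a site was surveyed."""

    mean_intensity: float
    max_intensity: float
    cumulative_intensity: float
    n_events: int
    n_event_days: int
    flags: set[str] = field(default_factory=set)


def aggregate_site_mhw(events: list[MHWEvent], survey_years: set[int]) -> SiteMHWSummary:
    """Restrict events to days falling in survey years and summarise.

    Metrics are computed over the retained daily intensities: the mean is
    duration-weighted by construction, the maximum and cumulative sums run
    over the same days.  With no retained event days all metrics are zero
    and the summary is flagged "no-events" (intensity stays a defined
    covariate at every site).
    """
    survey_years = set(int(y) for y in survey_years)
    if not survey_years:
        raise ValueError("survey_years must be non-empty")
    daily = []
    n_events = 0
    for ev in events:
        inside = np.asarray([d.year in survey_years for d in ev.daily_dates])
        if inside.any():
            n_events += 1
            daily.append(ev.daily_intensity[inside])
    if not daily:
        return SiteMHWSummary(0.0, 0.0, 0.0, 0, 0, {"no-events"})
    x = np.concatenate(daily)
    return SiteMHWSummary(float(x.mean()), float(x.max()), float(x.sum()), n_events, len(x))
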