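"""Telemetry cleaning: GPS-error screening, fix-interval harmonisation,
study-window clipping and individual-year inclusion filters.

All operations take and return "fix tables": pandas DataFrames with columns
``animal_id``, ``timestamp`` (tz-aware UTC), ``x``, ``y`` (projected metres).
Removed fixes and excluded groups are always reported with a machine-readable
reason, so kept + dropped reconstructs the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import Raster


@dataclass(frozen=True)
class StudyWindow:
    """Closure window (2020) and its month-day-matched counterpart years."""

    closure_start: date
    closure_end: date
    park_id: str | None = None

    def __post_init__(self) -> None:
        if self.closure_start >= self.closure_end:
            raise ValueError("closure_start must precede closure_end")
        for d in (self.closure_start, self.closure_end):
            if d.month == 2 and d.day == 29:
                raise ValueError("closure dates on Feb 29 cannot be matched across years")

    def window_for(self, year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
        start = pd.Timestamp(self.closure_start.replace(year=year), tz="UTC")
        # end of day on the closing date keeps the interval closed in days
        end = pd.Timestamp(self.closure_end.replace(year=year), tz="UTC") \
            + pd.Timedelta(days=1) - pd.Timedelta(seconds=1)
        return start, end


@dataclass(frozen=True)
class InclusionThresholds:
    """Cutoffs for keeping an individual-year in the analysis."""

    min_fixes: int = 30
    max_outside_fraction: float = 0.5
    min_mean_footprint: float = 0.02

    def __post_init__(self) -> None:
        if self.min_fixes < 2:
            raise ValueError("min_fixes must be >= 2")
        if not 0.0 <= self.max_outside_fraction <= 1.0:
            raise ValueError("max_outside_fraction must be in [0, 1]")


def _check_sorted(track: pd.DataFrame) -> None:
    for animal, grp in track.groupby("animal_id", sort=False):
        t = grp["timestamp"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) < np.timedelta64(0, "s")):
            raise ValueError(f"track for {animal!r} is not time-sorted")


def filter_gps_errors(
    track: pd.DataFrame,
    max_speed_mps: float = 10.0,
    duplicate_tolerance_s: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop duplicate-timestamp fixes and implausibly fast relocations.

    A fix is removed when its straight-line speed from the previous *retained*
    fix exceeds ``max_speed_mps``.  Returns (kept fixes, removal log); the log
    has one row per removed fix with columns animal_id, timestamp, reason.
    """
    _check_sorted(track)
    kept_idx: list = []
    log_rows: list[dict] = []
    for animal, grp in track.groupby("animal_id", sort=False):
        t = grp["timestamp"].to_numpy()
        x = grp["x"].to_numpy(dtype=float)
        y = grp["y"].to_numpy(dtype=float)
        last = None  # index into grp of last retained fix
        for i in range(len(grp)):
            if last is not None:
                dt = (t[i] - t[last]) / np.timedelta64(1, "s")
                if dt <= duplicate_tolerance_s:
                    log_rows.append({"animal_id": animal, "timestamp": t[i],
                                     "reason": "duplicate_timestamp"})
                    continue
                speed = np.hypot(x[i] - x[last], y[i] - y[last]) / dt
                if speed > max_speed_mps:
                    log_rows.append({"animal_id": animal, "timestamp": t[i],
                                     "reason": "speed_exceeded"})
                    continue
            kept_idx.append(grp.index[i])
            last = i
    log = pd.DataFrame(log_rows, columns=["animal_id", "timestamp", "reason"])
    return track.loc[kept_idx], log


def resample_track(
    track: pd.DataFrame,
    target_interval: timedelta = timedelta(hours=4),
    tolerance: timedelta = timedelta(minutes=30),
) -> pd.DataFrame:
    """Thin high-rate tracks to the target fix interval.

    Tracks whose median interval already is >= target are returned unchanged
    (original fix intervals are maintained for low-rate data).  Otherwise a
    greedy pass keeps, for each successive target time (last kept fix +
    target), the nearest fix within +/- tolerance, ties broken toward the
    earlier fix; across a gap the first fix beyond the window re-anchors the
    grid.  Retained fixes are therefore >= target - tolerance apart, which
    also makes the operation idempotent.
    """
    if target_interval <= timedelta(0):
        raise ValueError("target_interval must be positive")
    if tolerance < timedelta(0) or tolerance >= target_interval:
        raise ValueError("tolerance must be in [0, target_interval)")
    _check_sorted(track)
    target = int(target_interval.total_seconds() * 1e9)
    tol = int(tolerance.total_seconds() * 1e9)

    kept_idx: list = []
    for _, grp in track.groupby("animal_id", sort=False):
        t = pd.to_datetime(grp["timestamp"], utc=True).astype("int64").to_numpy()
        n = len(grp)
        if n == 0:
            continue
        if n > 1 and np.median(np.diff(t)) >= target:
            kept_idx.extend(grp.index)
            continue
        kept_idx.append(grp.index[0])
        last_t = t[0]
        while True:
            goal = last_t + target
            window = np.flatnonzero((t > last_t) & (t >= goal - tol) & (t <= goal + tol))
            if len(window):
                pick = window[np.argmin(np.abs(t[window] - goal))]  # tie -> earlier
            else:
                beyond = np.flatnonzero(t > goal + tol)
                if not len(beyond):
                    break
                pick = beyond[0]
            kept_idx.append(grp.index[pick])
            last_t = t[pick]
            if pick == n - 1:
                break
    return track.loc[kept_idx]


def clip_to_window(track: pd.DataFrame, window: StudyWindow, year: int) -> pd.DataFrame:
    """Keep fixes inside the closed study interval for ``year``; label them."""
    start, end = window.window_for(year)
    ts = pd.to_datetime(track["timestamp"], utc=True)
    out = track.loc[(ts >= start) & (ts <= end)].copy()
    out["year"] = year
    return out


def home_range_mean_footprint(polygon: BaseGeometry, footprint: Raster) -> float:
    """Mean footprint over raster cells whose centre falls in the polygon."""
    grid = footprint.grid
    X, Y = grid.center_mesh()
    minx, miny, maxx, maxy = polygon.bounds
    box = (X >= minx - grid.resolution) & (X <= maxx + grid.resolution) & \
          (Y >= miny - grid.resolution) & (Y <= maxy + grid.resolution)
    xs, ys = X[box], Y[box]
    if len(xs) == 0:
        return float("nan")
    inside = shapely.intersects_xy(polygon, xs, ys)
    if not inside.any():
        return float("nan")
    return float(footprint.values[box][inside].mean())


def apply_inclusion_filters(
    groups: dict[str, pd.DataFrame],
    park: BaseGeometry,
    footprint: Raster,
    thresholds: InclusionThresholds,
    home_ranges: dict[str, BaseGeometry],
) -> tuple[dict[str, pd.DataFrame], list[dict]]:
    """Apply the three individual-year inclusion rules.

    Rules, checked in order: (1) insufficient data (< min_fixes),
    (2) more than ``max_outside_fraction`` of fixes outside the park,
    (3) limited human footprint (home-range mean below ``min_mean_footprint``).
    Returns (kept groups, exclusion report); each excluded group appears once
    with the first rule it triggered.
    """
    if park is None:
        raise ValueError("park polygon is required for inclusion filtering")
    kept: dict[str, pd.DataFrame] = {}
    report: list[dict] = []
    for key, grp in groups.items():
        n = len(grp)
        if n < thresholds.min_fixes:
            report.append({"individual_year_id": key, "rule": "insufficient_data",
                           "value": n})
            continue
        inside = shapely.intersects_xy(park, grp["x"].to_numpy(), grp["y"].to_numpy())
        frac_outside = 1.0 - inside.mean()
        if frac_outside > thresholds.max_outside_fraction:
            report.append({"individual_year_id": key, "rule": "outside_park",
                           "value": float(frac_outside)})
            continue
        hr = home_ranges.get(key)
        if hr is None:
            raise ValueError(f"no home range supplied for group {key!r}")
        mean_fp = home_range_mean_footprint(hr, footprint)
        if not np.isfinite(mean_fp) or mean_fp < thresholds.min_mean_footprint:
            report.append({"individual_year_id": key, "rule": "limited_footprint",
                           "value": float(mean_fp)})
            continue
        kept[key] = grp
    return kept, report
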