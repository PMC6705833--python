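"""Aggregation of outlying days into epochs and media-search windows.

Consecutive outlying days are treated as one temporal event ("epoch"):
a burst of attention to a page typically spans several adjacent days as
news coverage propagates across time zones and languages. Each epoch
carries its peak daily pageview count, the date of that peak, a rank
(1 = highest peak across all epochs) and a media-correlate search
window extending one day on either side of the epoch to absorb time-zone
and lag effects. Identifying the correlates themselves is a manual step;
this module only emits the date windows and the report skeleton.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections.abc import Iterable

import pandas as pd

from ._dates import format_mdy
from .errors import IntegrityError, ParameterError

__all__ = ["Epoch", "merge_consecutive_dates", "build_epochs", "media_window", "epoch_report"]

_ONE_DAY = dt.timedelta(days=1)


@dataclasses.dataclass(frozen=True)
class Epoch:
    """A maximal run of calendar-consecutive outlying days."""

    start: dt.date
    end: dt.date
    peak_views: int
    peak_date: dt.date
    rank: int

    def __post_init__(self):
        if self.end < self.start:
            raise ParameterError("epoch end precedes start")
        if not self.start <= self.peak_date <= self.end:
            raise IntegrityError("peak date outside epoch")

    @property
    def members(self) -> list[dt.date]:
        n = (self.end - self.start).days + 1
        return [self.start + i * _ONE_DAY for i in range(n)]

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


def merge_consecutive_dates(dates: Iterable[dt.date]) -> list[tuple[dt.date, dt.date]]:
    """Collapse a set of days into maximal runs of adjacent calendar days.

    A gap of exactly one day joins two days into the same run; a gap of
    two or more days starts a new run. Returns chronologically sorted
    (start, end) pairs, inclusive.
    """
    days = sorted({_as_date(d) for d in dates})
    runs: list[tuple[dt.date, dt.date]] = []
    for day in days:
        if runs and day - runs[-1][1] == _ONE_DAY:
            runs[-1] = (runs[-1][0], day)
        else:
            runs.append((day, day))
    return runs


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return pd.Timestamp(value).date()


def build_epochs(outliers, series: pd.Series) -> list[Epoch]:
    """Build ranked epochs from flagged dates and the observed series.

    ``outliers`` is either an :class:`~wikianomaly.anomaly.OutlierResult`
    or an iterable of dates. Peaks are the maximum observed value over
    each run's member days; ranks order epochs by descending peak, ties
    broken by earlier start date. The returned list is chronological.
    """
    if hasattr(outliers, "flagged_dates"):
        dates = outliers.flagged_dates
    else:
        dates = [_as_date(d) for d in outliers]
    if not dates:
        return []
    lookup = {_as_date(ts): int(v) for ts, v in series.items()}
    missing = [d for d in dates if d not in lookup]
    if missing:
        raise IntegrityError(f"outlier dates outside the series range: {missing[:5]}")

    runs = merge_consecutive_dates(dates)
    provisional = []
    for start, end in runs:
        members = [(lookup[start + i * _ONE_DAY], start + i * _ONE_DAY)
                   for i in range((end - start).days + 1)]
        peak_views = max(v for v, _ in members)
        peak_date = min(d for v, d in members if v == peak_views)
        provisional.append((start, end, peak_views, peak_date))

    by_peak = sorted(provisional, key=lambda t: (-t[2], t[0]))
    ranks = {(start, end): r for r, (start, end, _, _) in enumerate(by_peak, start=1)}
    return [
        Epoch(start, end, peak_views, peak_date, ranks[(start, end)])
        for start, end, peak_views, peak_date in provisional
    ]


def media_window(epoch: Epoch) -> tuple[dt.date, dt.date]:
    """Search window: one day before the epoch to one day after it."""
    return epoch.start - _ONE_DAY, epoch.end + _ONE_DAY


def epoch_report(epochs: Iterable[Epoch]) -> pd.DataFrame:
    """Tabular epoch report, chronologically ordered.

    Columns mirror the published report style: epoch index, date range
    (unpadded M/D/YYYY), highest observed pageview, rank, media window
    bounds, and an empty correlates column for manual annotation.
    Input order does not matter; the report is normalized by start date.
    """
    epochs = sorted(epochs, key=lambda e: e.start)
    if not epochs:
        raise ParameterError("at least one epoch is required")
    rows = []
    for i, e in enumerate(epochs, start=1):
        w0, w1 = media_window(e)
        dates = format_mdy(e.start) if e.start == e.end else (
            f"{format_mdy(e.start)}–{format_mdy(e.end)}"
        )
        rows.append(
            {
                "epoch": i,
                "dates": dates,
                "peak_views": e.peak_views,
                "peak_date": e.peak_date.isoformat(),
                "rank": e.rank,
                "window_start": w0.isoformat(),
                "window_end": w1.isoformat(),
                "correlates": "",
            }
        )
    return pd.DataFrame(rows)
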