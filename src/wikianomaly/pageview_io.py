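"""Readers, writers and aggregations for Wikimedia pageview exports.

The Langviews tool reports daily all-platform pageview counts for one
page across every language localization that hosts it; Massviews does
the same for every page in a category. Both are distributed as
human-formatted delimited text (spreadsheet exports), so this module
tolerates thousands separators, mixed date styles, and both the *long*
layout (one row per date/language) and the *wide* layout (one row per
language, one column per date).

A panel's missing (date, language) cells mean *zero* recorded views,
not missing data: the export tools omit zero-traffic days.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from ._dates import parse_date
from .errors import InputFormatError, IntegrityError, ParameterError

__all__ = [
    "PageviewPanel",
    "read_langviews",
    "write_langviews",
    "read_massviews",
    "aggregate_daily_total",
    "language_shares",
    "category_share",
    "series_summary",
    "mean_daily_views",
    "read_daily_total",
    "write_daily_total",
]

_LANGUAGE_HEADERS = {"language", "lang", "wiki", "locale", "localization"}
_VIEW_HEADERS = {"views", "pageviews", "count", "total", "views_sum"}


def _parse_count(raw, where: str) -> int:
    """Parse an integer view count, stripping thousands separators."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        raise InputFormatError(f"missing view count at {where}")
    s = str(raw).strip().replace(",", "").replace(" ", "").replace(" ", "")
    if s in ("", "nan"):
        raise InputFormatError(f"missing view count at {where}")
    try:
        value = int(float(s)) if "." in s else int(s)
    except ValueError as exc:
        raise InputFormatError(f"unparseable view count {raw!r} at {where}") from exc
    if "." in s and float(s) != value:
        raise InputFormatError(f"non-integer view count {raw!r} at {where}")
    if value < 0:
        raise InputFormatError(f"negative view count {raw!r} at {where}")
    return value


@dataclasses.dataclass(frozen=True)
class PageviewPanel:
    """Per-(page, language) daily view counts over a contiguous date range.

    Parameters
    ----------
    data
        Long-format frame with columns ``date`` (datetime64), ``page``,
        ``language`` and ``views`` (non-negative int64). The (date, page,
        language) key is unique.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"date", "page", "language", "views"}
        if not required.issubset(self.data.columns):
            raise ParameterError(f"panel frame must have columns {sorted(required)}")
        if len(self.data) == 0:
            raise ParameterError("panel must contain at least one record")
        if (self.data["views"] < 0).any():
            raise IntegrityError("panel contains negative view counts")
        if self.data.duplicated(["date", "page", "language"]).any():
            raise IntegrityError("duplicate (date, page, language) records in panel")

    @property
    def date_range(self) -> tuple[dt.date, dt.date]:
        dates = self.data["date"]
        return dates.min().date(), dates.max().date()

    @property
    def languages(self) -> list[str]:
        return sorted(self.data["language"].unique())

    @property
    def pages(self) -> list[str]:
        return sorted(self.data["page"].unique())

    @property
    def grand_total(self) -> int:
        return int(self.data["views"].sum())

    def dense(self) -> pd.DataFrame:
        """Zero-filled (language, page) x date matrix over the full range.

        Canonical form for equality checks: two panels describing the
        same traffic compare equal here even if one stores explicit
        zero rows and the other omits them.
        """
        start, end = self.date_range
        full = pd.date_range(start, end, freq="D")
        wide = self.data.pivot_table(
            index=["page", "language"], columns="date", values="views",
            aggfunc="sum", fill_value=0,
        )
        return wide.reindex(columns=full, fill_value=0).astype("int64")

    def daily_total(self) -> pd.Series:
        """Total views per day over the panel's own range (zeros filled)."""
        start, end = self.date_range
        full = pd.date_range(start, end, freq="D", name="date")
        per_day = self.data.groupby("date")["views"].sum()
        return per_day.reindex(full, fill_value=0).astype("int64").rename("views")


def _sniff_frame(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:  # delimiter sniffing or tokenization failure
        raise InputFormatError(f"could not parse {path} as delimited text: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _is_date_header(h: str) -> bool:
    try:
        parse_date(h)
        return True
    except InputFormatError:
        return False


def read_langviews(path, page_label: str | None = None) -> PageviewPanel:
    """Read a Langviews-style export into a :class:`PageviewPanel`.

    Both layouts are auto-detected by header sniffing:

    * long — columns containing ``date``, a language column and a views
      column (plus, optionally, a ``page`` column);
    * wide — a language column followed by one column per date.

    ``page_label`` names the page the file describes; if the file has
    its own ``page`` column that column wins.
    """
    df = _sniff_frame(path)
    lower = {c.lower(): c for c in df.columns}

    records = []
    if "date" in lower and (_VIEW_HEADERS & set(lower)):
        date_col = lower["date"]
        views_col = lower[next(h for h in lower if h in _VIEW_HEADERS)]
        lang_col = lower.get(next((h for h in lower if h in _LANGUAGE_HEADERS), ""), None)
        page_col = lower.get("page")
        for i, row in enumerate(df.itertuples(index=False), start=2):
            row = dict(zip(df.columns, row))
            where = f"{path}:row {i}"
            day = parse_date(row[date_col])
            views = _parse_count(row[views_col], where)
            lang = str(row[lang_col]).strip() if lang_col else "en"
            page = str(row[page_col]).strip() if page_col else (page_label or "page")
            records.append((day, page, lang, views))
    else:
        # wide layout: one row per language, one column per date
        date_cols = [c for c in df.columns if _is_date_header(c)]
        if not date_cols:
            raise InputFormatError(
                f"{path}: unrecognized layout (no date column and no date-named headers)"
            )
        non_date = [c for c in df.columns if c not in date_cols]
        lang_col = next(
            (c for c in non_date if c.lower() in _LANGUAGE_HEADERS),
            non_date[0] if non_date else None,
        )
        if lang_col is None:
            raise InputFormatError(f"{path}: wide layout lacks a language column")
        page = page_label or "page"
        for i, row in enumerate(df.itertuples(index=False), start=2):
            row = dict(zip(df.columns, row))
            lang = str(row[lang_col]).strip()
            for c in date_cols:
                raw = row[c]
                if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                    continue  # omitted cell = zero traffic
                views = _parse_count(raw, f"{path}:row {i}, column {c!r}")
                records.append((parse_date(c), page, lang, views))

    if not records:
        raise InputFormatError(f"{path}: no pageview records found")

    data = pd.DataFrame(records, columns=["date", "page", "language", "views"])
    data["date"] = pd.to_datetime(data["date"])
    data["views"] = data["views"].astype("int64")

    dup = data.duplicated(["date", "page", "language"], keep=False)
    if dup.any():
        conflict = (
            data[dup].groupby(["date", "page", "language"])["views"].nunique() > 1
        )
        if conflict.any():
            key = conflict[conflict].index[0]
            raise IntegrityError(
                f"{path}: conflicting duplicate counts for (date, page, language)={key}"
            )
        data = data.drop_duplicates(["date", "page", "language"])

    return PageviewPanel(data.sort_values(["date", "page", "language"]).reset_index(drop=True))


def write_langviews(panel: PageviewPanel, path, layout: str = "long") -> None:
    """Write a panel as canonical long CSV or a wide per-language matrix."""
    path = Path(path)
    if layout == "long":
        out = panel.data.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
    elif layout == "wide":
        dense = panel.dense()
        dense.columns = [d.strftime("%Y-%m-%d") for d in dense.columns]
        # one file describes one page; fold the page level away
        dense = dense.droplevel("page")
        dense.index.name = "language"
        dense.to_csv(path)
    else:
        raise ParameterError(f"unknown layout {layout!r} (expected 'long' or 'wide')")


def read_massviews(path) -> pd.DataFrame:
    """Read a Massviews-style per-page totals export.

    Returns a frame with columns ``page`` and ``views`` (one row per
    page, integer totals).
    """
    df = _sniff_frame(path)
    if len(df) == 0:
        raise InputFormatError(f"{path}: empty category export")
    lower = {c.lower(): c for c in df.columns}
    page_col = lower.get("page") or lower.get("title") or df.columns[0]
    views_col = next((lower[h] for h in lower if h in _VIEW_HEADERS), df.columns[-1])
    if page_col == views_col:
        raise InputFormatError(f"{path}: cannot distinguish page and views columns")
    rows = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        rows.append((str(row[page_col]).strip(), _parse_count(row[views_col], f"{path}:row {i}")))
    out = pd.DataFrame(rows, columns=["page", "views"])
    return out.groupby("page", as_index=False)["views"].sum()


def _normalize_title(title: str) -> str:
    return str(title).strip().replace(" ", "_")


def category_share(table: pd.DataFrame, target_pages: Iterable[str]) -> float:
    """Fraction of a category's total views attributable to target pages."""
    targets = {_normalize_title(t) for t in target_pages}
    grand = int(table["views"].sum())
    if grand == 0:
        raise ParameterError("category table has zero total views")
    hit = int(table.loc[table["page"].map(_normalize_title).isin(targets), "views"].sum())
    return hit / grand


def aggregate_daily_total(
    panels: Iterable[PageviewPanel], zero_fill: bool = False
) -> pd.Series:
    """Collapse one or more panels to a single univariate daily-total series.

    Every page and language is summed per calendar day. Panels must
    share one date range unless ``zero_fill`` is set, in which case they
    are reindexed onto the union range with zeros outside their own.
    """
    panels = list(panels)
    if not panels:
        raise ParameterError("at least one panel is required")
    ranges = {p.date_range for p in panels}
    if len(ranges) > 1 and not zero_fill:
        raise IntegrityError(
            f"panels cover different date ranges {sorted(ranges)}; pass zero_fill=True "
            "to reindex onto the union"
        )
    start = min(r[0] for r in ranges)
    end = max(r[1] for r in ranges)
    full = pd.date_range(start, end, freq="D", name="date")
    total = pd.Series(0, index=full, dtype="int64", name="views")
    for p in panels:
        total = total.add(p.daily_total().reindex(full, fill_value=0), fill_value=0)
    return total.astype("int64")


def language_shares(
    panels: Iterable[PageviewPanel], top_k: int = 15, other_label: str = "Other"
) -> pd.DataFrame:
    """Per-language totals and fractional shares with an "Other" rollup.

    Languages are ranked by descending total views; ranks beyond
    ``top_k`` are folded into a single ``other_label`` bucket appended
    last. Totals are exact integer sums, so the table's grand total
    equals the panels' grand total.
    """
    if top_k < 1:
        raise ParameterError("top_k must be >= 1")
    panels = list(panels)
    if not panels:
        raise ParameterError("at least one panel is required")
    data = pd.concat([p.data for p in panels], ignore_index=True)
    totals = (
        data.groupby("language")["views"].sum().astype("int64")
        .sort_values(ascending=False)
        .sort_index(kind="stable")  # tie-break: language code ascending
        .sort_values(ascending=False, kind="stable")
    )
    grand = int(totals.sum())
    head = totals.iloc[:top_k]
    tail = int(totals.iloc[top_k:].sum())
    rows = [(lang, int(v)) for lang, v in head.items()]
    if tail > 0:
        rows.append((other_label, tail))
    out = pd.DataFrame(rows, columns=["language", "views"])
    out["share"] = out["views"] / grand
    return out


def series_summary(series: pd.Series) -> Mapping[str, int]:
    """Grand total, day count and nearest-integer mean of a daily series."""
    total = int(series.sum())
    days = int(len(series))
    if days == 0:
        raise ParameterError("empty series")
    return {"total_views": total, "n_days": days, "mean_daily_views": mean_daily_views(total, days)}


def mean_daily_views(total_views: int, n_days: int) -> int:
    """Average daily views, rounded to the nearest integer."""
    if n_days <= 0:
        raise ParameterError("n_days must be positive")
    return int(round(total_views / n_days))


def write_daily_total(series: pd.Series, path) -> None:
    """Write a univariate daily-total series as a two-column ISO-dated CSV."""
    out = series.rename("views").rename_axis("date").reset_index()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_daily_total(path) -> pd.Series:
    """Read the CSV written by :func:`write_daily_total`."""
    df = _sniff_frame(path)
    lower = {c.lower(): c for c in df.columns}
    if "date" not in lower:
        raise InputFormatError(f"{path}: daily-total file lacks a date column")
    views_col = next((lower[h] for h in lower if h in _VIEW_HEADERS), df.columns[-1])
    dates = pd.to_datetime([parse_date(d) for d in df[lower["date"]]])
    values = [_parse_count(v, f"{path}:row {i + 2}") for i, v in enumerate(df[views_col])]
    series = pd.Series(values, index=pd.DatetimeIndex(dates, name="date"), name="views")
    return series.sort_index()
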