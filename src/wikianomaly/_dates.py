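"""Date parsing helpers for human-formatted pageview exports.

Exports in the wild mix ISO dates (2016-06-04) with US-style M/D/YYYY
(6/4/2016, no zero padding), and date *ranges* joined by a hyphen, an
en dash or an em dash. Everything is normalized here so the rest of the
package only ever sees ``datetime.date``.
"""

from __future__ import annotations

import datetime as dt
import re

from .errors import InputFormatError

_DASHES = re.compile(r"[‒–—―]")  # figure/en/em/horizontal dashes

_ISO = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_MDY = re.compile(r"^\d{1,2}/\d{1,2}/\d{4}$")


def parse_date(token: str | dt.date) -> dt.date:
    """Parse a single calendar day in ISO or M/D/YYYY form."""
    if isinstance(token, dt.datetime):
        return token.date()
    if isinstance(token, dt.date):
        return token
    s = str(token).strip()
    if _ISO.match(s):
        return dt.date.fromisoformat(s)
    if _MDY.match(s):
        m, d, y = (int(p) for p in s.split("/"))
        return dt.date(y, m, d)
    raise InputFormatError(f"unparseable date: {token!r}")


def parse_date_range(text: str) -> tuple[dt.date, dt.date]:
    """Parse ``"3/29/2016-4/1/2016"`` (any dash variant) or a single day."""
    s = _DASHES.sub("-", str(text).strip())
    if " to " in s:
        parts = [p.strip() for p in s.split(" to ")]
    elif "/" in s and s.count("-") == 1:
        parts = [p.strip() for p in s.split("-")]
    elif "/" not in s and s.count("-") == 5:  # two ISO dates joined by '-'
        parts = [s[:10].strip(), s[11:].strip()]
    else:
        parts = [s]
    if len(parts) == 1:
        d = parse_date(parts[0])
        return d, d
    start, end = parse_date(parts[0]), parse_date(parts[1])
    if end < start:
        raise InputFormatError(f"date range ends before it starts: {text!r}")
    return start, end


def date_span(start: dt.date, end: dt.date) -> list[dt.date]:
    """All calendar days from start to end inclusive."""
    n = (end - start).days
    if n < 0:
        raise InputFormatError("end date precedes start date")
    return [start + dt.timedelta(days=i) for i in range(n + 1)]


def format_mdy(day: dt.date) -> str:
    """Render a day in the unpadded M/D/YYYY style used in epoch reports."""
    return f"{day.month}/{day.day}/{day.year}"
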