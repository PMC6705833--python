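import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wikianomaly import PageviewPanel


@pytest.fixture
def rng():
    return np.random.default_rng(20180630)


def make_panel(rows):
    """Build a panel from (date, page, language, views) tuples."""
    data = pd.DataFrame(rows, columns=["date", "page", "language", "views"])
    data["date"] = pd.to_datetime(data["date"])
    data["views"] = data["views"].astype("int64")
    return PageviewPanel(data)


def random_panel(rng, n_languages=5, n_days=10, page="P", start=dt.date(2016, 1, 1)):
    """Random small panel with ~30% of cells omitted (implicit zeros)."""
    rows = []
    for d in range(n_days):
        day = start + dt.timedelta(days=d)
        for l in range(n_languages):
            if rng.random() < 0.7:
                rows.append((day, page, f"l{l}", int(rng.integers(0, 500))))
    if not rows:  # panel must be non-empty
        rows.append((start, page, "l0", 1))
    return make_panel(rows)


@pytest.fixture
def daily_series():
    """Deterministic 1,096-day series: weekly pattern + level shift."""
    pattern = np.array([120, 150, 130, 110, 80, 20, 30])
    n = 1096
    values = 10_000 + pattern[np.arange(n) % 7]
    values = values + np.where(np.arange(n) >= 546, 800, 0)
    index = pd.date_range("2015-07-01", periods=n, freq="D")
    return pd.Series(values.astype(float), index=index)
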