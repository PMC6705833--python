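"""Synthetic pageview panels and clickstream files with known truth.

The generator reproduces the statistical structure the detector assumes
in daily Wikipedia traffic: a multi-language panel whose daily total is
a slowly drifting level times a weekly pattern, with overdispersed count
noise and occasional injected attention spikes. Defaults mirror the
scale of the sepsis/septic-shock study period: 1,096 days, a mean total
of 18,756 views/day spread over 16 language buckets with power-law
shares, ±4–9% weekly swing, one +8% level shift midway, and
negative-binomial noise with total coefficient of variation around 7%.

Every dataset is bit-reproducible from (spec, seed), and every generator
returns a :class:`TruthRecord` carrying the injected anomalies and the
true seasonal/trend components so detector output can be scored against
ground truth.

The module also ships, machine-readable, the reference table of 25
outlying sepsis/septic-shock traffic epochs (July 2015 – June 2018) used
as a worked example throughout the test-suite.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from ._dates import date_span, parse_date_range
from .errors import ParameterError
from .pageview_io import PageviewPanel

__all__ = [
    "Anomaly",
    "PanelSpec",
    "ClickstreamSpec",
    "TruthRecord",
    "noise_scale",
    "gen_pageview_panel",
    "gen_clickstream",
    "category_map_frame",
    "reference_epoch_table",
    "reference_outlier_dates",
]

_WEEKDAY_OFFSETS = (0.04, 0.05, 0.04, 0.03, 0.00, -0.09, -0.07)  # Mon..Sun, sums to 0


@dataclasses.dataclass(frozen=True)
class Anomaly:
    """An injected attention spike.

    ``magnitude`` is in units of the panel's analytic noise scale for
    ``mode="additive"`` and a multiplier of the day's expected total for
    ``mode="multiplicative"``.
    """

    day: int
    duration: int = 1
    magnitude: float = 8.0
    mode: str = "additive"

    def __post_init__(self):
        if self.duration < 1:
            raise ParameterError("anomaly duration must be >= 1")
        if self.mode not in ("additive", "multiplicative"):
            raise ParameterError("anomaly mode must be 'additive' or 'multiplicative'")


def _power_law_shares(n: int, exponent: float) -> np.ndarray:
    raw = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return raw / raw.sum()


@dataclasses.dataclass(frozen=True)
class PanelSpec:
    """Parameters of a synthetic multi-language daily pageview panel."""

    start: dt.date = dt.date(2015, 7, 1)
    n_days: int = 1096
    page: str = "Sepsis"
    languages: tuple[str, ...] = (
        "en", "ja", "ru", "de", "es", "it", "fr", "pt", "zh", "pl",
        "nl", "ar", "tr", "ko", "sv", "other",
    )
    mean_daily_total: float = 18756.0
    share_exponent: float = 1.4          # power-law decay of language base rates
    weekday_offsets: tuple[float, ...] = _WEEKDAY_OFFSETS
    trend_changes: tuple[tuple[int, float], ...] = ((0, 1.00), (546, 1.08))
    noise: str = "nb"                    # "nb" | "lognormal" | "none"
    dispersion: float = 200.0            # negative-binomial size parameter
    sigma_log: float = 0.07              # log-scale sd for the lognormal option
    anomalies: tuple[Anomaly, ...] = tuple(
        Anomaly(day=d) for d in (45, 150, 255, 360, 470, 580, 690, 800, 910, 1020)
    )

    def __post_init__(self):
        if self.n_days < 14:
            raise ParameterError("n_days must be >= 14 (two weekly cycles)")
        if self.mean_daily_total <= 0:
            raise ParameterError("mean_daily_total must be positive")
        if len(self.weekday_offsets) != 7:
            raise ParameterError("weekday_offsets must have 7 entries (Mon..Sun)")
        if abs(sum(self.weekday_offsets)) > 1e-9:
            raise ParameterError("weekday_offsets must sum to zero")
        if self.noise not in ("nb", "lognormal", "none"):
            raise ParameterError("noise must be 'nb', 'lognormal' or 'none'")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be positive")
        if not self.trend_changes or self.trend_changes[0][0] != 0:
            raise ParameterError("trend_changes must start at day 0")
        for a in self.anomalies:
            if not 0 <= a.day < self.n_days or a.day + a.duration > self.n_days:
                raise ParameterError(f"anomaly at day {a.day} falls outside the date range")

    @property
    def language_rates(self) -> dict[str, float]:
        shares = _power_law_shares(len(self.languages), self.share_exponent)
        return {lang: self.mean_daily_total * s for lang, s in zip(self.languages, shares)}

    def trend_level(self, day: int) -> float:
        level = self.trend_changes[0][1]
        for start, value in self.trend_changes:
            if day >= start:
                level = value
        return level

    def relative_level(self, day: int) -> float:
        weekday = (self.start + dt.timedelta(days=day)).weekday()
        return self.trend_level(day) + self.weekday_offsets[weekday]

    def expected_total(self, day: int) -> float:
        return self.mean_daily_total * self.relative_level(day)


def noise_scale(spec: PanelSpec) -> float:
    """Analytic sd of the daily total at the baseline level (1.0).

    With independent per-language negative binomials whose size is
    proportional to the language share, the total behaves like a single
    NB(mean M, size r): var = M + M^2 / r.
    """
    m = spec.mean_daily_total
    if spec.noise == "nb":
        return math.sqrt(m + m * m / spec.dispersion)
    if spec.noise == "lognormal":
        return m * math.sqrt(math.exp(spec.sigma_log**2) - 1)
    return 0.0


@dataclasses.dataclass
class TruthRecord:
    """Ground truth serialized alongside every generated dataset."""

    seed: int
    anomalies: list[dict]                      # [{date, added_views}] per injected day
    seasonal: list[float] | None = None        # true additive seasonal per day
    trend: list[float] | None = None           # true trend level (views) per day
    expected_totals: list[float] | None = None
    category_totals: dict[str, int] | None = None

    @property
    def anomaly_dates(self) -> list[dt.date]:
        return [dt.date.fromisoformat(a["date"]) for a in self.anomalies]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _largest_remainder_split(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion an integer total across weights, exactly conserving it."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def gen_pageview_panel(spec: PanelSpec, seed: int) -> tuple[PageviewPanel, TruthRecord]:
    """Generate a reproducible multi-language panel with known truth.

    Per-language daily means are ``rate_l * (trend level + weekday
    offset)``. With ``noise="nb"`` each cell is a negative-binomial draw
    with size proportional to the language share; with ``noise="none"``
    the deterministic expected totals are apportioned exactly across
    languages. Anomalies add deterministic extra views (to the largest
    language) on top of the noise so the injected mass is known exactly.
    """
    rng = np.random.default_rng(seed)
    langs = list(spec.languages)
    rates = np.array([spec.language_rates[l] for l in langs])
    shares = rates / rates.sum()
    days = np.arange(spec.n_days)
    levels = np.array([spec.relative_level(int(d)) for d in days])
    mean_matrix = np.outer(levels, rates)  # (day, language)

    if spec.noise == "none":
        views = np.vstack(
            [
                _largest_remainder_split(int(round(spec.expected_total(int(d)))), rates)
                for d in days
            ]
        )
    elif spec.noise == "nb":
        size = spec.dispersion * shares  # per-language NB size parameter
        p = size / (size + mean_matrix)
        views = rng.negative_binomial(n=np.broadcast_to(size, mean_matrix.shape), p=p)
    else:  # lognormal on the log scale, variance-matched mean
        mu = np.log(mean_matrix) - spec.sigma_log**2 / 2
        views = np.rint(rng.lognormal(mean=mu, sigma=spec.sigma_log)).astype(int)

    scale = noise_scale(spec)
    anomaly_records = []
    for a in spec.anomalies:
        for d in range(a.day, a.day + a.duration):
            if a.mode == "additive":
                added = int(round(a.magnitude * scale)) if scale > 0 else int(round(a.magnitude))
            else:
                added = int(round((a.magnitude - 1.0) * spec.expected_total(d)))
            views[d, 0] += added
            anomaly_records.append(
                {"date": (spec.start + dt.timedelta(days=d)).isoformat(), "added_views": added}
            )

    dates = pd.date_range(spec.start, periods=spec.n_days, freq="D")
    data = pd.DataFrame(
        {
            "date": np.repeat(dates, len(langs)),
            "page": spec.page,
            "language": np.tile(langs, spec.n_days),
            "views": views.reshape(-1).astype("int64"),
        }
    )
    panel = PageviewPanel(data)

    m = spec.mean_daily_total
    weekday0 = spec.start.weekday()
    seasonal = [m * spec.weekday_offsets[(weekday0 + int(d)) % 7] for d in days]
    trend = [m * spec.trend_level(int(d)) for d in days]
    truth = TruthRecord(
        seed=seed,
        anomalies=anomaly_records,
        seasonal=seasonal,
        trend=trend,
        expected_totals=[spec.expected_total(int(d)) for d in days],
    )
    return panel, truth


@dataclasses.dataclass(frozen=True)
class ClickstreamSpec:
    """Parameters of a synthetic clickstream dump for one target page."""

    target: str = "Sepsis"
    n_inbound: int = 200_000
    categories: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "Search engines": 0.55,
            "People": 0.18,
            "Conditions": 0.12,
            "Medical topics": 0.07,
            "Unknown/refererless": 0.05,
            "Other external": 0.03,
        }
    )
    category_pages: Mapping[str, Sequence[str]] = dataclasses.field(
        default_factory=lambda: {
            "People": ("Muhammad_Ali", "Patty_Duke", "Jim_Henson"),
            "Conditions": ("Bacteremia", "Gangrene", "Septic_shock", "Pneumonia"),
            "Medical topics": ("Antibiotic", "Intensive_care_medicine", "SOFA_score"),
        }
    )
    outbound_total: int = 12_000
    outbound_pages: tuple[str, ...] = (
        "Septic_shock", "Infection", "SIRS", "Bacteremia", "Antibiotic",
        "Lactic_acidosis", "Hypotension", "Sequential_organ_failure_assessment",
        "Immunosuppression", "Fever", "Blood_culture", "Vasopressor",
    )

    def __post_init__(self):
        if abs(sum(self.categories.values()) - 1.0) > 1e-9:
            raise ParameterError("category proportions must sum to 1")
        if self.n_inbound < 1:
            raise ParameterError("n_inbound must be >= 1")


_RESERVED_BY_CATEGORY = {
    "Search engines": "other-search",
    "Other external": "other-external",
    "Unknown/refererless": "other-empty",
    "Other Wikimedia": "other-internal",
    "Other": "other-other",
}


def gen_clickstream(
    spec: ClickstreamSpec, seed: int, path=None
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate clickstream edges with multinomial category totals.

    Inbound mass is split across categories by one multinomial draw (the
    drawn totals are the recorded truth, so conservation checks are
    exact); page-backed categories are further split across their pages
    with power-law weights. Outbound link edges follow the same scheme.
    If ``path`` is given the edges are also written as a headerless TSV.
    """
    rng = np.random.default_rng(seed)
    cats = list(spec.categories)
    counts = rng.multinomial(spec.n_inbound, [spec.categories[c] for c in cats])
    truth_totals = {c: int(k) for c, k in zip(cats, counts) if k > 0}

    rows = []
    for cat, total in zip(cats, counts):
        if total == 0:
            continue
        if cat in _RESERVED_BY_CATEGORY:
            rows.append((_RESERVED_BY_CATEGORY[cat], spec.target, "external", int(total)))
        else:
            pages = list(spec.category_pages.get(cat, (f"{cat}_page",)))
            weights = _power_law_shares(len(pages), 1.0)
            split = rng.multinomial(int(total), weights)
            for page, n in zip(pages, split):
                if n > 0:
                    rows.append((page, spec.target, "link", int(n)))

    out_weights = _power_law_shares(len(spec.outbound_pages), 1.0)
    out_split = rng.multinomial(spec.outbound_total, out_weights)
    for page, n in zip(spec.outbound_pages, out_split):
        if n > 0:
            rows.append((spec.target, page, "link", int(n)))

    edges = pd.DataFrame(rows, columns=["prev", "curr", "type", "n"])
    if path is not None:
        edges.to_csv(path, sep="\t", header=False, index=False)
    truth = TruthRecord(seed=seed, anomalies=[], category_totals=truth_totals)
    return edges, truth


def category_map_frame(spec: ClickstreamSpec) -> pd.DataFrame:
    """The (title, category) map matching a clickstream spec's pages."""
    rows = [
        (page, cat)
        for cat, pages in spec.category_pages.items()
        for page in pages
    ]
    return pd.DataFrame(rows, columns=["title", "category"])


# ---------------------------------------------------------------------------
# Reference epoch table: the 25 outlying sepsis/septic-shock traffic epochs
# reported for July 2015 - June 2018, with peak daily pageviews and ranks.
# ---------------------------------------------------------------------------

_REFERENCE_EPOCHS = (
    (1, "12/6/2015", 22657, 23),
    (2, "1/20/2016", 25243, 17),
    (3, "1/26/2016", 41784, 4),
    (4, "3/26/2016", 22000, 24),
    (5, "3/29/2016–4/1/2016", 92305, 2),
    (6, "4/4/2016", 25048, 18),
    (7, "6/4/2016–6/13/2016", 224927, 1),
    (8, "9/12/2016–9/17/2016", 38644, 5),
    (9, "9/21/2016", 24674, 20),
    (10, "9/28/2016", 36984, 7),
    (11, "10/3/2016–10/4/2016", 29553, 12),
    (12, "10/7/2016", 23256, 21),
    (13, "12/3/2016", 23023, 22),
    (14, "3/10/2017", 30768, 10),
    (15, "3/16/2017", 28667, 14),
    (16, "7/4/2017", 36600, 8),
    (17, "9/5/2017", 26685, 15),
    (18, "9/11/2017", 30664, 11),
    (19, "9/13/2017", 25532, 16),
    (20, "10/21/2017–10/24/2017", 71140, 3),
    (21, "10/30/2017", 25030, 19),
    (22, "11/19/2017", 21555, 25),
    (23, "1/11/2018", 28857, 13),
    (24, "1/18/2018–1/19/2018", 32630, 9),
    (25, "3/12/2018", 37142, 6),
)


def reference_epoch_table() -> pd.DataFrame:
    """Machine-readable reference epochs: start, end, peak views, rank."""
    rows = []
    for idx, span, peak, rank in _REFERENCE_EPOCHS:
        start, end = parse_date_range(span)
        rows.append({"epoch": idx, "start": start, "end": end, "peak_views": peak, "rank": rank})
    return pd.DataFrame(rows)


def reference_outlier_dates() -> list[dt.date]:
    """The reference epochs expanded into individual outlying days."""
    days: list[dt.date] = []
    for _, span, _, _ in _REFERENCE_EPOCHS:
        start, end = parse_date_range(span)
        days.extend(date_span(start, end))
    return sorted(days)
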