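"""Seasonal Hybrid ESD (S-H-ESD) outlier detection for daily count series.

The detector combines two ideas:

1. a robust additive decomposition ``x_t = s_t + m_t + r_t`` where the
   seasonal component ``s_t`` is a fixed periodic pattern estimated by
   per-phase medians (one value per weekday for daily data) and the
   trend ``m_t`` is a *piecewise median*: the median of the
   deseasonalized series within consecutive fixed-length windows
   (182 days by default), and
2. a generalized extreme studentized deviate (ESD) test on the
   residuals ``r_t`` in which the mean and standard deviation of the
   classical test are replaced by the median and the (normal-consistent)
   median absolute deviation.

Medians make both stages resistant to the very spikes the test is meant
to find: a handful of extreme days cannot drag the trend or inflate the
scale estimate and thereby mask one another.

The ESD critical value at step ``k`` of ``n`` observations is

    lambda_k = (n - k) * t_{p, n-k-1} / sqrt((n-k-1 + t^2) * (n-k+1))

with ``p = 1 - alpha/(n-k+1)`` for one-tailed detection and
``p = 1 - alpha/(2(n-k+1))`` for two-tailed. The reported outliers are
the first ``k*`` removal candidates, ``k*`` being the largest step whose
studentized statistic exceeds its critical value.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

__all__ = [
    "SHESDParams",
    "Decomposition",
    "OutlierResult",
    "BPResult",
    "ESDStep",
    "ESDResult",
    "seasonal_estimate",
    "piecewise_median_trend",
    "decompose",
    "esd_lambda",
    "robust_esd",
    "shesd_detect",
    "breusch_pagan",
    "plot_detection",
]

Direction = Literal["upper", "lower", "both"]


@dataclasses.dataclass(frozen=True)
class SHESDParams:
    """Tuning parameters of the detector.

    period
        Days per seasonal cycle; 7 for daily web traffic.
    span_days
        Length of each piecewise-median trend window, in days.
    alpha
        Significance level of the ESD test. 0.01 is deliberately
        conservative for noisy daily data.
    max_outlier_fraction
        Upper bound on the number of outliers the ESD test may report,
        as a fraction of the series length.
    direction
        "upper" flags only days exceeding expectation (the default for
        traffic-surge detection); "lower" and "both" are available.
    """

    period: int = 7
    span_days: int = 182
    alpha: float = 0.01
    max_outlier_fraction: float = 0.10
    direction: Direction = "upper"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.period < 2:
            raise ParameterError("period must be >= 2")
        if self.span_days < self.period:
            raise ParameterError("span_days must be >= period")
        if not 0 < self.max_outlier_fraction <= 0.49:
            raise ParameterError("max_outlier_fraction must lie in (0, 0.49]")
        if self.direction not in ("upper", "lower", "both"):
            raise ParameterError("direction must be 'upper', 'lower' or 'both'")


def _as_values_index(series) -> tuple[np.ndarray, pd.DatetimeIndex | None]:
    """Coerce input to (float array, optional daily DatetimeIndex)."""
    if isinstance(series, pd.Series):
        values = series.to_numpy(dtype=float)
        index = pd.DatetimeIndex(series.index)
        if len(index) > 1:
            deltas = np.diff(index.values).astype("timedelta64[D]")
            if not (deltas == np.timedelta64(1, "D")).all():
                raise ParameterError("series index must be contiguous calendar days")
        return values, index
    values = np.asarray(series, dtype=float)
    if values.ndim != 1:
        raise ParameterError("series must be one-dimensional")
    return values, None


def seasonal_estimate(values: Sequence[float], period: int = 7) -> np.ndarray:
    """Robust periodic seasonal component.

    The series is first detrended with a centered rolling median of
    window ``period``; each phase (weekday) then gets the median of its
    detrended observations, and the phase values are re-centered to sum
    to zero over one period. The component is constant across cycles.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2 * period:
        raise ParameterError(f"need at least {2 * period} observations for period {period}")
    rough_trend = (
        pd.Series(x).rolling(period, center=True, min_periods=1).median().to_numpy()
    )
    detrended = x - rough_trend
    phases = np.arange(n) % period
    phase_medians = np.array([np.median(detrended[phases == p]) for p in range(period)])
    phase_medians -= phase_medians.mean()
    return phase_medians[phases]


def piecewise_median_trend(values: Sequence[float], span_days: int = 182) -> np.ndarray:
    """Trend as the median within consecutive windows of ``span_days``.

    Windows are anchored at the series start. A trailing partial window
    shorter than half a span is merged into the preceding window rather
    than carrying its own (statistically meaningless) median.
    """
    x = np.asarray(values, dtype=float)
    if span_days < 1:
        raise ParameterError("span_days must be >= 1")
    n = len(x)
    if n == 0:
        raise ParameterError("empty series")
    starts = list(range(0, n, span_days))
    if len(starts) > 1 and n - starts[-1] < span_days / 2:
        starts.pop()
    trend = np.empty(n, dtype=float)
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else n
        trend[s:e] = np.median(x[s:e])
    return trend


@dataclasses.dataclass(frozen=True)
class Decomposition:
    """Additive (seasonal, trend, residual) triple.

    ``seasonal + trend + residual`` reconstructs the observed series to
    machine precision by construction (the residual is defined as the
    difference).
    """

    observed: np.ndarray
    seasonal: np.ndarray
    trend: np.ndarray
    residual: np.ndarray
    index: pd.DatetimeIndex | None = None

    @property
    def fitted(self) -> np.ndarray:
        return self.seasonal + self.trend

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "observed": self.observed,
                "seasonal": self.seasonal,
                "trend": self.trend,
                "residual": self.residual,
            }
        )
        if self.index is not None:
            frame.insert(0, "date", self.index)
        return frame


def decompose(series, params: SHESDParams | None = None) -> Decomposition:
    """Robust additive decomposition into seasonal + piecewise-median trend."""
    params = params or SHESDParams()
    values, index = _as_values_index(series)
    seasonal = seasonal_estimate(values, params.period)
    trend = piecewise_median_trend(values - seasonal, params.span_days)
    residual = values - seasonal - trend
    return Decomposition(values, seasonal, trend, residual, index)


def esd_lambda(n: int, k: int, alpha: float, direction: Direction = "upper") -> float:
    """Critical value of the generalized ESD test at removal step ``k``."""
    df = n - k - 1
    if df < 1:
        raise ParameterError(f"degenerate degrees of freedom (n={n}, k={k})")
    m = n - k + 1
    p = 1 - alpha / m if direction in ("upper", "lower") else 1 - alpha / (2 * m)
    t = stats.t.ppf(p, df)
    return (n - k) * t / math.sqrt((df + t * t) * (n - k + 1))


@dataclasses.dataclass(frozen=True)
class ESDStep:
    """One removal step of the iterative ESD procedure."""

    order: int          # k = 1, 2, ...
    index: int          # position in the original residual vector
    value: float        # residual value removed
    stat: float         # studentized deviation C_k
    critical: float     # lambda_k


@dataclasses.dataclass(frozen=True)
class ESDResult:
    steps: tuple[ESDStep, ...]
    k_star: int

    @property
    def flagged(self) -> tuple[ESDStep, ...]:
        return self.steps[: self.k_star]

    @property
    def flagged_indices(self) -> np.ndarray:
        return np.array([s.index for s in self.flagged], dtype=int)


def _center_scale(x: np.ndarray, center: str, scale: str) -> tuple[float, float]:
    if center == "median":
        c = float(np.median(x))
    elif center == "mean":
        c = float(np.mean(x))
    else:
        raise ParameterError("center must be 'median' or 'mean'")
    dev = np.abs(x - np.median(x))
    if scale == "mad":
        s = 1.4826 * float(np.median(dev))
        if s == 0.0:  # degenerate: fall back to mean absolute deviation
            s = float(np.mean(dev))
    elif scale == "sd":
        s = float(np.std(x, ddof=1))
    else:
        raise ParameterError("scale must be 'mad' or 'sd'")
    return c, s


def robust_esd(
    residuals: Sequence[float],
    alpha: float = 0.01,
    k_max: int | None = None,
    direction: Direction = "upper",
    center: str = "median",
    scale: str = "mad",
) -> ESDResult:
    """Generalized ESD with median/MAD studentization.

    At each step the most extreme remaining residual (relative to the
    current median and 1.4826-scaled MAD) is recorded and removed; after
    ``k_max`` steps the reported outliers are the first ``k*``
    candidates, where ``k*`` is the largest step whose statistic
    exceeded its critical value. Ties in the argmax break toward the
    earliest position. With ``center="mean", scale="sd"`` the procedure
    reduces to the classical generalized ESD test.
    """
    x = np.asarray(residuals, dtype=float)
    n = len(x)
    if k_max is None:
        k_max = max(1, int(np.floor(0.10 * n)))
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    if n <= k_max + 2:
        raise ParameterError(f"series too short (n={n}) for k_max={k_max}")

    active = np.ones(n, dtype=bool)
    steps: list[ESDStep] = []
    for k in range(1, k_max + 1):
        current = x[active]
        c, s = _center_scale(current, center, scale)
        if s <= 0:
            warnings.warn(
                "residual scale is zero (all remaining values equal); "
                "stopping ESD iteration early",
                stacklevel=2,
            )
            break
        if direction == "upper":
            deviations = current - c
        elif direction == "lower":
            deviations = c - current
        else:
            deviations = np.abs(current - c)
        stats_k = deviations / s
        local = int(np.argmax(stats_k))  # first maximum = earliest position
        global_idx = int(np.flatnonzero(active)[local])
        steps.append(
            ESDStep(
                order=k,
                index=global_idx,
                value=float(x[global_idx]),
                stat=float(stats_k[local]),
                critical=esd_lambda(n, k, alpha, direction),
            )
        )
        active[global_idx] = False

    k_star = max((s.order for s in steps if s.stat > s.critical), default=0)
    return ESDResult(tuple(steps), k_star)


@dataclasses.dataclass(frozen=True)
class OutlierResult:
    """Outcome of S-H-ESD detection on one daily series.

    ``table`` has one row per flagged day, in detection order, with the
    observed value, the fitted expectation (seasonal + trend), the
    residual, the ESD statistic, its critical value and the detection
    step ``k``.
    """

    table: pd.DataFrame
    decomposition: Decomposition
    params: SHESDParams
    n: int

    @property
    def n_flagged(self) -> int:
        return len(self.table)

    @property
    def flagged_dates(self) -> list:
        if "date" not in self.table.columns:
            return sorted(self.table["position"].tolist())
        return sorted(pd.to_datetime(self.table["date"]).dt.date.tolist())


def shesd_detect(series, params: SHESDParams | None = None) -> OutlierResult:
    """Run the full S-H-ESD pipeline: decompose, then robust ESD."""
    params = params or SHESDParams()
    dec = decompose(series, params)
    n = len(dec.observed)
    k_max = int(np.floor(params.max_outlier_fraction * n))
    if k_max >= 1:
        esd = robust_esd(
            dec.residual, alpha=params.alpha, k_max=k_max, direction=params.direction
        )
        flagged = esd.flagged
    else:
        flagged = ()

    rows = []
    fitted = dec.fitted
    for step in flagged:
        i = step.index
        row = {
            "position": i,
            "observed": dec.observed[i],
            "expected": fitted[i],
            "residual": dec.residual[i],
            "stat": step.stat,
            "critical": step.critical,
            "k": step.order,
        }
        if dec.index is not None:
            row["date"] = dec.index[i]
        rows.append(row)
    columns = ["position", "observed", "expected", "residual", "stat", "critical", "k"]
    if dec.index is not None:
        columns = ["date"] + columns
    table = pd.DataFrame(rows, columns=columns)
    return OutlierResult(table=table, decomposition=dec, params=params, n=n)


@dataclasses.dataclass(frozen=True)
class BPResult:
    """Breusch-Pagan Lagrange-multiplier test of residual homoscedasticity."""

    lm: float
    df: int
    pvalue: float


def breusch_pagan(residuals: Sequence[float], fitted: Sequence[float]) -> BPResult:
    """Breusch-Pagan test: squared residuals regressed on fitted values.

    The LM statistic is ``n * R^2`` of the auxiliary regression, referred
    to a chi-square distribution with one degree of freedom (one
    regressor). The null hypothesis is constant residual variance.
    """
    r = np.asarray(residuals, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if len(r) != len(f):
        raise ParameterError("residuals and fitted values must have equal length")
    if len(r) < 3:
        raise ParameterError("need at least 3 observations")
    if np.ptp(f) == 0:
        raise ParameterError("fitted values are constant; auxiliary regression undefined")
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan

    lm, pvalue, _, _ = het_breuschpagan(r, sm.add_constant(f))
    return BPResult(lm=float(lm), df=1, pvalue=float(pvalue))


def plot_detection(series: pd.Series, result: OutlierResult, path, log_scale: bool = True):
    """Export an annotated series plot with flagged days highlighted.

    The vertical axis defaults to a log scale so large spikes do not
    flatten the rest of the series.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(11, 4))
    ax.plot(series.index, series.to_numpy(), lw=0.7, color="steelblue", label="daily views")
    trend = result.decomposition.trend
    ax.plot(series.index, trend, color="black", lw=1.5, label="median spans")
    if result.n_flagged and "date" in result.table.columns:
        ax.scatter(
            pd.to_datetime(result.table["date"]),
            result.table["observed"],
            color="crimson",
            zorder=3,
            s=18,
            label="outlying days",
        )
    if log_scale:
        ax.set_yscale("log")
    ax.set_ylabel("pageviews (log scale)" if log_scale else "pageviews")
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
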