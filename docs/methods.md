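# Methods

## Problem and model

The package analyses daily pageview counts for a small set of Wikipedia
pages (summed over all language localizations) to find days on which
public attention was significantly elevated, and to characterize how
readers arrive at and leave those pages. Daily web traffic has three
structural features the detector must respect: a weekly rhythm, a slowly
moving baseline, and occasional very large spikes driven by news events.
The observed total is modelled additively,

    x_t = s_t + m_t + r_t,

with a *periodic* seasonal component (one value per weekday, constant
over the whole series) and a *piecewise-median* trend (one median per
consecutive fixed-length window). Both components are estimated with
medians so that the spikes we are trying to detect cannot distort the
baseline they are measured against.

### Seasonal component

The series is first roughly detrended with a centered rolling median of
window equal to the period (7 days): over one full cycle this rolling
median is a constant for any exactly periodic signal, so the weekly
pattern survives intact while level shifts are removed except within
half a window of a change point. Each weekday then receives the median
of its detrended observations, and the seven values are re-centered to
sum to zero. Per-phase medians over ~52+ cycles are unaffected by the
few contaminated days around level shifts and by injected spikes, which
is why the decomposition recovers exactly-periodic-plus-piecewise-constant
inputs with identically zero residual (a test asserts this).

A full LOESS-based evolving seasonal (as in STL) is deliberately not
used: the periodic per-phase-median seasonal matches the fixed-seasonal
setting of the hybrid-ESD procedure, is exactly reproducible, and keeps
the pipeline free of smoother version sensitivity. The decomposition
function is the single place an evolving seasonal could be substituted.

### Trend component

The deseasonalized series is partitioned into consecutive windows of
`span_days` (default 182, i.e. half a year — appropriate when the trend
is slight and the series spans a few years) anchored at the series
start; the trend on each day is the median of its window. A trailing
partial window shorter than half a span is merged into the preceding
window: a 1,096-day series yields six 182-day windows with the 4
remainder days absorbed into the sixth (a 4-day median would be
meaningless). The residual is defined as `x_t - s_t - m_t`, so the
additive identity holds to machine precision on every input.

### Robust generalized ESD

The residuals are screened by a generalized extreme studentized deviate
test with robust studentization: at step `k` the center is the median
and the scale is the median absolute deviation scaled by 1.4826 (normal
consistency) of the residuals not yet removed. If the MAD is zero the
mean absolute deviation from the median is used; if that is also zero
all remaining residuals are equal and the procedure stops with a
warning and no further candidates. For upper-tail detection the
statistic is `C_k = max (r_i - median) / scale`; the flagged set is the
first `k*` removals where `k*` is the largest `k` with
`C_k > lambda_k`, and

    lambda_k = (n-k) t_{p, n-k-1} / sqrt((n-k-1+t^2)(n-k+1)),
    p = 1 - alpha/(n-k+1)  (one-tailed),  1 - alpha/(2(n-k+1))  (two-tailed).

Argmax ties break toward the earliest day (determinism). With
`center="mean", scale="sd"` the routine reduces to the textbook
classical generalized ESD; a test verifies step-by-step agreement with
an independently written brute-force implementation. `k_max` is
`floor(max_outlier_fraction * n)` with a default ceiling of 10% of the
series. No multiplicity correction beyond the ESD's own
`alpha/(n-k+1)` schedule is applied.

Parameters and defaults: `period = 7` days (natural for daily web
traffic; configurable), `span_days = 182`, `alpha = 0.01`
(conservative, intended to surface only meaningful surges in noisy
daily data), `direction = "upper"` (days significantly *below*
expectation are not sought by default), `max_outlier_fraction = 0.10`.

### Residual diagnostic

A Breusch–Pagan test (squared residuals regressed on the fitted values;
LM = n·R² against χ² with 1 df, via statsmodels) screens for
heteroscedasticity; a small p-value suggests a variance-stabilizing
transformation should be applied before detection. The one-regressor
form is the natural choice when the only fitted quantity is the
decomposition itself.

## Epochs

Outlying days separated by exactly one calendar day belong to the same
epoch; a two-day gap starts a new one. Each epoch records its peak daily
pageview count and peak date, a rank by descending peak (ties broken by
earlier start date), and a media-correlate search window from one day
before the epoch to one day after it, to absorb time-zone and lag
effects. Identifying the correlates (news database queries) is a manual
step; the report emits an empty `correlates` column for annotation.

## Clickstream

Monthly dumps of `(prev, curr, type, n)` referrer–resource pairs are
filtered to edges touching the target pages, merged across months by
exact key-wise summation, and inbound referrers rolled up into curated
categories. Reserved aggregate tokens map to fixed display categories
(`other-search` → "Search engines", `other-empty` →
"Unknown/refererless", etc.); page titles match after space/underscore
normalization, case-sensitively. Only `type == "link"` edges count as
internal outbound referrals for the top-k ranking (ties by title). The
Sankey export re-checks that inbound link weights sum exactly to the raw
inbound counts and raises an internal error otherwise. The category
taxonomy is user-supplied configuration, not hard-coded.

## Synthetic data generator

The generator emulates the structure above with known truth: per-day,
per-language means `rate_l × (trend level + weekday offset)` where the
language rates decay as a power law (exponent 1.4 over 16 buckets, top
share ≈ 0.44) scaled to a mean daily total of 18,756 views over 1,096
days from 2015-07-01; weekday offsets of +3–5% (weekdays) and −7–9%
(weekends) summing to zero; a single +8% level change at day 546 (a
multiple of both the weekly period and the 182-day span, so the exact
additive model is recoverable); and independent negative-binomial noise
per language with size proportional to share, giving a daily-total
standard deviation of ≈1,333 (cv ≈ 7%) at size 200 — counts are
overdispersed, as real traffic is. Ten single-day spikes of 8× the
noise scale are injected on fixed days by default, added
deterministically on top of the noise so the injected mass is known
exactly. A log-normal noise option exists for misspecification testing,
and a zero-noise mode apportions the deterministic expected totals
exactly across languages (largest-remainder rounding). Everything is
bit-reproducible from `(spec, seed)`.

What the generator does **not** emulate: annual seasonality, correlated
noise across days, language-specific event signatures (spikes are
injected into the aggregate via the largest language), gradual
multi-week attention decay after events, and missing-data artifacts.
Passing the recovery tests therefore shows the detector finds isolated
additive surges of the stated magnitude under overdispersed stationary
noise — not that it would resolve overlapping or slowly decaying events
in real traffic.

## Monte-Carlo behavior and a known limitation

On the generator's defaults, injected-spike recovery over 100 seeds has
mean sensitivity 1.0 with mean false flags ≈ 0.14/series (max 1), and
the robust ESD's any-flag rate over 1,000 null standard-normal residual
series at `alpha = 0.01` is ≈ 1–2% (both recomputed by
`scripts/acceptance.py`).

The ESD critical values assume normal residual tails. Under the
generator's negative-binomial noise the residuals are mildly
right-skewed (skewness ≈ 0.14 at size 200), and a one-tailed test at a
4σ-scale threshold is sensitive to exactly that tail: end-to-end, about
10–12% of *null* count panels produce at least one upper-tail flag — an
order-of-magnitude inflation over the nominal rate that a Cornish–Fisher
tail correction predicts from the skewness alone. The script reports
this rate (`type1_nb_panel_rate`) alongside the normal-null rate.
Practically: for strongly skewed counts, consider a log or square-root
transformation before detection (the Breusch–Pagan diagnostic helps
decide), and treat isolated single-day flags barely above `lambda_k`
with caution.

## Numerical and design notes

- Detection is invariant to adding a constant to the series and
  equivariant under positive scaling (tested).
- Window anchoring at the series start and earliest-day tie-breaks make
  results independent of input ordering and platform.
- Missing (date, language) cells in pageview exports are zero views,
  not missing data, matching the export tools' omission of zero-traffic
  days; both long and wide export layouts are auto-detected, and
  thousands separators and dash variants are normalized at parse time.
- Language-share tables use exact integer sums, so the "Other" rollup
  conserves the grand total exactly; shares are derived quantities.
- Time zones: calendar days are taken as reported (UTC day boundaries);
  no adjustment is attempted at daily granularity.
- The replication checks against the original multi-language exports
  (grand total 20,557,055; 65/23 languages; 43.1% English; 47 flagged
  days) require those exports under `data/supplementary/` and report a
  failure naming that path when run without them. The 47-day count is
  additionally sensitive to decomposition variant details; agreement is
  reported, never tuned.
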