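import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wikianomaly import (
    SHESDParams,
    breusch_pagan,
    decompose,
    esd_lambda,
    robust_esd,
    shesd_detect,
)
from wikianomaly.anomaly import piecewise_median_trend, seasonal_estimate
from wikianomaly.errors import ParameterError

PATTERN = np.array([120.0, 150.0, 130.0, 110.0, 80.0, 20.0, 30.0])


def weekly_series(n, base=10_000.0, shift_at=None, shift=0.0):
    values = base + PATTERN[np.arange(n) % 7]
    if shift_at is not None:
        values = values + np.where(np.arange(n) >= shift_at, shift, 0.0)
    return values


class TestSeasonalEstimate:
    def test_constant_series_has_no_seasonality(self):
        assert np.allclose(seasonal_estimate(np.full(70, 5.0), 7), 0.0)

    def test_exact_weekly_pattern_recovered_to_centering(self):
        x = weekly_series(364)
        seasonal = seasonal_estimate(x, 7)
        truth = PATTERN - PATTERN.mean()
        assert np.allclose(seasonal[:7], truth, atol=1e-12)

    def test_known_offsets_recovered_under_noise(self, rng):
        x = weekly_series(364) + rng.normal(0, 5.0, 364)
        seasonal = seasonal_estimate(x, 7)
        truth = PATTERN - PATTERN.mean()
        assert np.max(np.abs(seasonal[:7] - truth)) < 5.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ParameterError):
            seasonal_estimate(np.arange(13.0), 7)


class TestPiecewiseMedianTrend:
    def test_constant_series(self):
        assert np.allclose(piecewise_median_trend(np.full(400, 3.5), 182), 3.5)

    def test_two_level_series_forced_by_construction(self):
        x = np.where(np.arange(364) < 182, 100.0, 200.0)
        trend = piecewise_median_trend(x, 182)
        assert np.allclose(trend[:182], 100.0) and np.allclose(trend[182:], 200.0)

    @pytest.mark.parametrize("n,span", [(50, 7), (365, 30), (1096, 182), (200, 182)])
    def test_matches_bruteforce_window_median_oracle(self, rng, n, span):
        x = rng.normal(0, 10, n)
        trend = piecewise_median_trend(x, span)
        # independent oracle: explicit window list with the merge rule
        import statistics

        bounds = []
        s = 0
        while s < n:
            bounds.append([s, min(s + span, n)])
            s += span
        if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < span / 2:
            bounds[-2][1] = n
            bounds.pop()
        for lo, hi in bounds:
            expected = statistics.median(x[lo:hi].tolist())
            assert np.allclose(trend[lo:hi], expected)


class TestDecompose:
    def test_exact_model_gives_zero_residual(self):
        x = weekly_series(1092, shift_at=546, shift=800.0)
        dec = decompose(x, SHESDParams())
        assert np.max(np.abs(dec.residual)) < 1e-9

    def test_additive_identity_on_noisy_series(self, rng):
        x = weekly_series(1096) + rng.normal(0, 300, 1096)
        dec = decompose(x)
        recon = dec.seasonal + dec.trend + dec.residual
        assert np.max(np.abs(recon - dec.observed)) < 1e-9 * np.abs(x).max()

    def test_spike_mass_lands_in_residual_not_trend(self):
        x = weekly_series(364)
        mad = 1.4826 * np.median(np.abs(x - np.median(x)))
        clean_trend = decompose(x).trend
        x_spiked = x.copy()
        x_spiked[100] += 10 * mad
        dec = decompose(x_spiked)
        assert np.allclose(dec.trend, clean_trend)  # medians ignore the spike
        assert dec.residual[100] > 8 * mad


@settings(derandomize=True, max_examples=40)
@given(
    st.lists(
        st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        min_size=14,
        max_size=400,
    )
)
def test_reconstruction_identity_property(values):
    """seasonal + trend + residual reproduces any observed series."""
    x = np.asarray(values)
    dec = decompose(x, SHESDParams(span_days=60))
    scale = max(1.0, np.abs(x).max())
    assert np.max(np.abs(dec.seasonal + dec.trend + dec.residual - x)) < 1e-9 * scale


class TestESDLambda:
    def test_matches_independent_t_quantile_evaluation(self):
        # closed form evaluated independently with R's qt (and the classic
        # tabulated value for n=54): lambda_1 = 3.158794
        assert esd_lambda(54, 1, 0.05, "both") == pytest.approx(3.158794, abs=1e-5)

    def test_strictly_decreasing_in_k(self):
        lams = [esd_lambda(100, k, 0.01, "upper") for k in range(1, 20)]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_grows_as_alpha_vanishes(self):
        # lambda_1 increases monotonically as alpha shrinks, approaching its
        # finite ceiling (n-k)/sqrt(n-k+1)
        lams = [esd_lambda(100, 1, a, "upper") for a in (0.05, 0.01, 1e-4, 1e-8, 1e-12)]
        assert all(a < b for a, b in zip(lams, lams[1:]))
        assert lams[-1] > 6.0
        assert lams[-1] < 99 / np.sqrt(101)

    def test_degenerate_df_rejected(self):
        with pytest.raises(ParameterError):
            esd_lambda(5, 4, 0.05)


def brute_force_classical_gesd(values, alpha, k_max, direction="both"):
    """Textbook generalized ESD, written independently of the package.

    Tracks explicit index lists and recomputes mean/sd from scratch at
    every step; returns (k_star, [(index, C_k, lambda_k)]).
    """
    remaining = list(range(len(values)))
    steps = []
    n = len(values)
    for k in range(1, k_max + 1):
        sub = [values[i] for i in remaining]
        m = sum(sub) / len(sub)
        sd = math.sqrt(sum((v - m) ** 2 for v in sub) / (len(sub) - 1))
        if direction == "upper":
            devs = [v - m for v in sub]
        elif direction == "lower":
            devs = [m - v for v in sub]
        else:
            devs = [abs(v - m) for v in sub]
        j = max(range(len(sub)), key=lambda i: (devs[i], -i))
        c_k = devs[j] / sd
        df = n - k - 1
        p = 1 - alpha / (n - k + 1) if direction in ("upper", "lower") else 1 - alpha / (
            2 * (n - k + 1)
        )
        t = stats.t.ppf(p, df)
        lam = (n - k) * t / math.sqrt((df + t * t) * (n - k + 1))
        steps.append((remaining[j], c_k, lam))
        remaining.pop(j)
    k_star = max((i + 1 for i, (_, c, lam) in enumerate(steps) if c > lam), default=0)
    return k_star, steps


class TestRobustESD:
    def test_all_equal_residuals_yield_no_outliers_with_warning(self):
        with pytest.warns(UserWarning, match="scale"):
            result = robust_esd(np.zeros(100), alpha=0.01, k_max=5)
        assert result.k_star == 0 and len(result.flagged) == 0

    def test_three_planted_extremes_exactly_flagged(self, rng):
        x = rng.standard_normal(100)
        planted = [7, 40, 83]
        for i in planted:
            x[i] = 15.0
        result = robust_esd(x, alpha=0.01, k_max=10, direction="upper")
        assert sorted(result.flagged_indices.tolist()) == planted

    @pytest.mark.parametrize("direction", ["upper", "both"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_classical_mode_matches_textbook_oracle(self, direction, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 50))
        x = rng.standard_normal(n)
        x[2] += 6.0
        x[7] -= 5.0
        k_max = min(8, n - 3)
        mine = robust_esd(x, alpha=0.05, k_max=k_max, direction=direction,
                          center="mean", scale="sd")
        k_star, steps = brute_force_classical_gesd(x.tolist(), 0.05, k_max, direction)
        assert mine.k_star == k_star
        for step, (idx, c, lam) in zip(mine.steps, steps):
            assert step.index == idx
            assert step.stat == pytest.approx(c, abs=1e-10)
            assert step.critical == pytest.approx(lam, abs=1e-10)

    def test_gross_outlier_does_not_mask_moderate_one(self, rng):
        x = rng.standard_normal(100)
        x[10], x[20] = 50.0, 8.0
        result = robust_esd(x, alpha=0.01, k_max=10, direction="upper")
        assert {10, 20}.issubset(set(result.flagged_indices.tolist()))

    def test_median_mad_resists_masking_where_mean_sd_fails(self):
        # ten planted values of 8 in n=60 inflate the sd enough that the
        # classical statistic never crosses its critical value within
        # k_max=3 steps, while median/MAD studentization flags all three.
        rng = np.random.default_rng(7)
        x = rng.standard_normal(60)
        for i in range(0, 60, 6):
            x[i] = 8.0
        robust = robust_esd(x, alpha=0.05, k_max=3, direction="upper")
        classical = robust_esd(x, alpha=0.05, k_max=3, direction="upper",
                               center="mean", scale="sd")
        assert robust.k_star == 3
        assert classical.k_star == 0


class TestSHESDDetect:
    def test_exact_model_yields_no_outliers(self, daily_series):
        result = shesd_detect(daily_series)
        assert result.n_flagged == 0

    def test_injected_spikes_recovered_exactly(self, daily_series, rng):
        noisy = daily_series + rng.normal(0, 200, len(daily_series))
        spikes = [100, 400, 700, 1000]
        noisy.iloc[spikes] += 8 * 200
        result = shesd_detect(noisy)
        expected = {daily_series.index[i].date() for i in spikes}
        assert set(result.flagged_dates) == expected
        assert (result.table["residual"] > 0).all()  # upper-tail invariant
        assert result.n_flagged <= int(0.10 * len(noisy))

    def test_detection_invariant_to_shift_and_positive_scale(self, daily_series, rng):
        noisy = daily_series + rng.normal(0, 200, len(daily_series))
        noisy.iloc[[300, 600]] += 2000
        base = shesd_detect(noisy).flagged_dates
        shifted = shesd_detect(noisy + 5_000).flagged_dates
        scaled = shesd_detect(noisy * 3.0).flagged_dates
        assert base == shifted == scaled

    def test_flag_cap_respects_max_outlier_fraction(self, daily_series, rng):
        noisy = daily_series + rng.normal(0, 50, len(daily_series))
        noisy.iloc[::15] += 5_000  # far more contamination than the cap
        params = SHESDParams(max_outlier_fraction=0.02)
        result = shesd_detect(noisy, params)
        assert 0 < result.n_flagged <= int(0.02 * len(noisy))


class TestBreuschPagan:
    def test_homoscedastic_null_not_rejected(self, rng):
        fitted = rng.normal(100, 10, 1000)
        residuals = rng.normal(0, 5, 1000)
        assert breusch_pagan(residuals, fitted).pvalue > 0.05

    def test_variance_proportional_to_fitted_rejected(self, rng):
        fitted = rng.uniform(10, 100, 1000)
        residuals = rng.normal(0, 0.3 * fitted, 1000)
        assert breusch_pagan(residuals, fitted).pvalue < 0.01

    def test_small_instance_matches_normal_equations_oracle(self):
        residuals = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 0.1])
        fitted = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        result = breusch_pagan(residuals, fitted)
        # independent oracle: explicit least squares on squared residuals
        u = residuals**2
        design = np.column_stack([np.ones(6), fitted])
        beta = np.linalg.solve(design.T @ design, design.T @ u)
        resid_aux = u - design @ beta
        r_squared = 1 - resid_aux @ resid_aux / ((u - u.mean()) @ (u - u.mean()))
        assert result.lm == pytest.approx(6 * r_squared, rel=1e-9)
        assert result.pvalue == pytest.approx(stats.chi2.sf(result.lm, 1), rel=1e-9)
        assert result.df == 1

    def test_constant_fitted_rejected(self):
        with pytest.raises(ParameterError, match="constant"):
            breusch_pagan(np.array([1.0, 2.0, 3.0]), np.full(3, 4.0))
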