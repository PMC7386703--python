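"""Lomb-Scargle periodogram, significance, sliding windows, circular stats."""
import warnings
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import lombscargle as scipy_lombscargle

from ovilog import rhythm, synth

ATTENUATION = np.sin(np.pi / 6) / (np.pi / 6)  # ±2-h mean of a 24-h cosine


def _tb_series(**kwargs):
    defaults = dict(n_days=60, sample_interval_min=10, mesor=39.6,
                    circadian_amplitude=1.0, noise_sd=0.15, seed=11)
    defaults.update(kwargs)
    cfg = synth.SeriesSynthConfig(**defaults)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cfg, synth.gen_series(cfg, "tb")


class TestLombScargle:
    def test_agrees_with_least_squares_oracle(self):
        # per-frequency sinusoid regression: power == SSR / (2 * variance)
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 216, 400))
        y = 1.3 * np.cos(2 * np.pi * t / 24 - 1.1) + rng.normal(0, 1.0, len(t))
        periods = np.array([3.0, 7.5, 12.0, 24.0, 29.0])
        pg = rhythm.lomb_scargle(t, y, periods_h=periods)
        var = np.var(y, ddof=1)
        yc = y - y.mean()
        for p_h, power in zip(pg.periods_h, pg.power):
            w = 2 * np.pi / p_h
            x_mat = np.column_stack([np.cos(w * t), np.sin(w * t)])
            beta, *_ = np.linalg.lstsq(x_mat, yc, rcond=None)
            ssr = yc @ yc - np.sum((yc - x_mat @ beta) ** 2)
            assert power == pytest.approx(ssr / (2 * var), rel=1e-8)

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 216, 300))
        y = rng.normal(0, 1, len(t)) + 0.8 * np.sin(2 * np.pi * t / 12)
        periods = np.linspace(3, 29, 40)
        pg = rhythm.lomb_scargle(t, y, periods_h=periods)
        ref = scipy_lombscargle(t, y - y.mean(), 2 * np.pi / periods) / np.var(y, ddof=1)
        np.testing.assert_allclose(pg.power, ref, rtol=1e-8)

    def test_pure_cosine_peaks_at_24h_grid_point(self):
        t = np.arange(1296) * (10 / 60.0)
        y = np.cos(2 * np.pi * t / 24.0)
        pg = rhythm.lomb_scargle(t, y)
        best, _ = pg.peak()
        grid_nearest = pg.periods_h[np.argmin(np.abs(pg.periods_h - 24.0))]
        assert best == grid_nearest

    def test_constant_series_zero_power(self):
        t = np.arange(100) * 0.5
        pg = rhythm.lomb_scargle(t, np.full(100, 39.6))
        assert not pg.power.any()

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 216, 200))
        y = rng.normal(0, 1, 200)
        periods = np.linspace(3, 29, 25)
        a = rhythm.lomb_scargle(t, y, periods_h=periods).power
        b = rhythm.lomb_scargle(t + 1000.0, y, periods_h=periods).power
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-9)

    def test_value_scaling_invariance(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 216, 200))
        y = rng.normal(0, 1, 200)
        periods = np.linspace(3, 29, 25)
        a = rhythm.lomb_scargle(t, y, periods_h=periods).power
        b = rhythm.lomb_scargle(t, 7.3 * y + 40.0, periods_h=periods).power
        np.testing.assert_allclose(a, b, rtol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            rhythm.lomb_scargle(np.arange(5.0), np.arange(5.0))


class TestSignificance:
    def test_zero_power_gives_p_one(self):
        pg = rhythm.Periodogram(np.array([24.0]), np.array([0.0]), 100, 50)
        assert rhythm.ls_significance(pg) == 1.0

    def test_strong_sinusoid_highly_significant(self):
        t = np.arange(1296) * (10 / 60.0)
        y = np.cos(2 * np.pi * t / 24.0) + np.random.default_rng(4).normal(0, 0.3, len(t))
        pg = rhythm.lomb_scargle(t, y)
        assert rhythm.ls_significance(pg) < 1e-6

    def test_formula_matches_permutation_test(self):
        # moderate-power case where both estimates are informative
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 72, 80))
        y = 0.55 * np.cos(2 * np.pi * t / 24) + rng.normal(0, 1, len(t))
        p_formula = rhythm.ls_significance(rhythm.lomb_scargle(t, y))
        p_perm = rhythm.permutation_pvalue(t, y, n_perm=400, seed=1)
        assert p_formula == pytest.approx(p_perm, abs=0.08)


class TestSlidingWindows:
    def test_noiseless_circadian_series_counts_and_period(self):
        _, tb = _tb_series(noise_sd=0.0)
        results = rhythm.sliding_window_rhythms(tb)
        assert len(results) == 52  # 60 days − 8 edge days
        assert all(r.significant for r in results)
        assert {r.best_period_rounded_h for r in results} == {24.0}

    def test_pure_ultradian_series_rounds_to_12(self):
        _, tb = _tb_series(n_days=12, circadian_amplitude=0.0,
                           ultradian12_amplitude=0.5, noise_sd=0.05, seed=3)
        results = rhythm.sliding_window_rhythms(tb)
        assert results and {r.best_period_rounded_h for r in results} == {12.0}

    def test_short_series_warns_and_returns_empty(self):
        _, tb = _tb_series(n_days=6)
        with pytest.warns(UserWarning, match="window"):
            assert rhythm.sliding_window_rhythms(tb) == []

    def test_hr_series_filtered_to_accepted_quality(self):
        cfg = synth.SeriesSynthConfig(n_days=10, mesor=110.0, circadian_amplitude=8.0,
                                      noise_sd=5.0, quality_mix=(0.3, 0.3, 0.2, 0.2), seed=5)
        hr = synth.gen_series(cfg, "hr")
        df = rhythm.prepare_series(hr)
        assert len(df) < len(hr)
        assert len(df) == sum(1 for m in hr if m.algo_quality <= 1)

    def test_partially_rhythmic_series_share(self):
        # rhythm present on the first 50 of 68 days; windows need a few
        # rhythmic days to lock onto 24 h, so the expected share of the 60
        # analyzed windows detecting the circadian period is ~80%
        cfg, tb = _tb_series(n_days=68, seed=21)
        flat_from = 50 * 144  # 10-min sampling
        rng = np.random.default_rng(9)
        flat = [synth.TbMeasurement(m.animal_id, m.time, 39.6 + float(rng.normal(0, 0.15)))
                for m in tb[flat_from:]]
        results = rhythm.sliding_window_rhythms(list(tb[:flat_from]) + flat)
        share = 100.0 * np.mean([r.significant and r.best_period_rounded_h == 24.0
                                 for r in results])
        assert share == pytest.approx(80.0, abs=5.0)


class TestRhythmProportions:
    def _result(self, day, period, sig=True):
        return rhythm.RhythmResult(date(2016, 7, day), period, period, 0.001 if sig else 0.5,
                                   sig, 1000)

    def test_all_circadian(self):
        res = [self._result(d, 24.0) for d in range(1, 11)]
        assert rhythm.rhythm_proportions(res) == {24.0: 100.0}

    def test_even_split(self):
        res = [self._result(d, 24.0) for d in range(1, 6)]
        res += [self._result(d, 12.0) for d in range(6, 11)]
        assert rhythm.rhythm_proportions(res) == {12.0: 50.0, 24.0: 50.0}

    def test_minor_classes_pooled_and_nonsignificant_in_denominator(self):
        res = [self._result(d, 24.0) for d in range(1, 18)]          # 17 windows at 24 h
        res.append(self._result(18, 8.5))                            # 1 minor class (< 5%)
        res += [self._result(d, 24.0, sig=False) for d in range(19, 22)]  # 3 silent
        out = rhythm.rhythm_proportions(res)
        assert out[24.0] == pytest.approx(100 * 17 / 21)
        assert out["other"] == pytest.approx(100 * 1 / 21)
        assert 8.5 not in out


class TestRollingSmooth:
    def test_constant_unchanged(self):
        t = np.arange(100) / 6.0
        np.testing.assert_allclose(rhythm.rolling_smooth(t, np.full(100, 5.0)), 5.0)

    def test_linear_interior_unchanged(self):
        t = np.arange(200) / 6.0
        y = 3.0 * t + 1.0
        sm = rhythm.rolling_smooth(t, y)
        interior = slice(13, -13)  # one window width from the edges
        np.testing.assert_allclose(sm[interior], y[interior], rtol=1e-9)

    def test_cosine_attenuation_closed_form(self):
        t = np.arange(24 * 60) / 60.0  # 1-min sampling over one day
        y = np.cos(2 * np.pi * t / 24.0)
        sm = rhythm.rolling_smooth(t, y)
        interior = (t > 4) & (t < 20) & (np.abs(y) > 0.2)  # avoid zero crossings
        ratio = sm[interior] / y[interior]
        np.testing.assert_allclose(ratio, ATTENUATION, atol=2e-3)


class TestDailyExtrema:
    def test_zenith_time_matches_acrophase(self):
        cfg, tb = _tb_series(noise_sd=0.0)
        df = rhythm.smooth_frame(rhythm.prepare_series(tb))
        extrema = rhythm.daily_extrema(df)
        acro_sec = cfg.acrophase_hour * 3600
        for e in extrema[1:-1]:
            z = e.zenith_time.hour * 3600 + e.zenith_time.minute * 60
            assert abs(z - acro_sec) <= 600 + 1  # within one 10-min sample

    def test_amplitude_attenuated_peak_to_trough(self):
        cfg, tb = _tb_series(noise_sd=0.0)
        df = rhythm.smooth_frame(rhythm.prepare_series(tb))
        extrema = rhythm.daily_extrema(df)
        amp = np.mean([e.amplitude for e in extrema[1:-1]])
        assert amp == pytest.approx(ATTENUATION * 2.0, rel=0.01)

    def test_constant_day_degenerate(self):
        _, tb = _tb_series(n_days=1, circadian_amplitude=0.0, noise_sd=0.0)
        df = rhythm.prepare_series(tb)
        df["smoothed"] = df["value"]
        (e,) = rhythm.daily_extrema(df)
        assert e.degenerate and e.amplitude == 0.0

    def test_low_coverage_day_skipped(self):
        _, tb = _tb_series(n_days=2)
        df = rhythm.smooth_frame(rhythm.prepare_series(tb[: 144 + 30]))  # day 2 nearly empty
        with pytest.warns(UserWarning, match="coverage"):
            extrema = rhythm.daily_extrema(df)
        assert len(extrema) == 1


class TestCircularMeanTime:
    def test_wraparound_midnight(self):
        mean_sec, _ = rhythm.circular_mean_time([23 * 3600.0, 1 * 3600.0])
        assert min(mean_sec, 86400 - mean_sec) == pytest.approx(0.0, abs=1e-6)

    def test_single_time_zero_sd(self):
        mean_sec, sd = rhythm.circular_mean_time([19 * 3600 + 46 * 60.0])
        assert mean_sec == pytest.approx(19 * 3600 + 46 * 60) and sd == 0.0

    def test_antipodal_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            rhythm.circular_mean_time([6 * 3600.0, 18 * 3600.0])

    @settings(derandomize=True, max_examples=25)
    @given(
        st.lists(st.floats(0, 86399), min_size=2, max_size=8),
        st.floats(-43200, 43200),
    )
    def test_rotation_equivariance(self, secs, shift):
        try:
            base, sd0 = rhythm.circular_mean_time(secs)
        except ValueError:
            return  # antipodal input: undefined either way
        rotated, sd1 = rhythm.circular_mean_time([(s + shift) % 86400 for s in secs])
        delta = (rotated - base - shift) % 86400
        assert min(delta, 86400 - delta) == pytest.approx(0.0, abs=1e-3)
        assert sd1 == pytest.approx(sd0, abs=1e-6)
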