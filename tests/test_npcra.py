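"""Nonparametric circadian indicators: profiles, L5/M10, RA, IS, IV."""

import numpy as np
import pytest

import actipipe as ap
from actipipe.core import ConfigurationError, UndefinedValueError
from actipipe.npcra import DailyProfile, WindowDesignation

MS_PER_DAY = 86_400_000


def hourly_series(activity_per_hour, n_days):
    """ActivitySeries with 60 s epochs repeating a 24-value hourly pattern."""
    pattern = np.repeat(np.asarray(activity_per_hour, dtype=float), 60)
    values = np.tile(pattern, n_days)
    starts = np.arange(len(values), dtype=np.int64) * 60000
    return ap.ActivitySeries("PIM(ENMO)", 60, starts, values)


class TestMeanProfile:
    def test_identical_days(self):
        day = np.abs(np.sin(np.arange(24))) + 0.1
        series = hourly_series(day, 3)
        profile = ap.mean_profile(series, 60)
        assert profile.n_days_used == 3
        assert np.allclose(profile.bins, np.repeat(day, 60))

    def test_two_day_average(self):
        a = hourly_series(np.zeros(24), 1)
        b = ap.ActivitySeries("PIM(ENMO)", 60,
                              a.epoch_starts + MS_PER_DAY,
                              np.full(1440, 2.0))
        series = ap.ActivitySeries(
            "PIM(ENMO)", 60,
            np.concatenate([a.epoch_starts, b.epoch_starts]),
            np.concatenate([a.values, b.values]))
        profile = ap.mean_profile(series, 60)
        assert np.allclose(profile.bins, 1.0)

    def test_matches_brute_force_day_slices(self, cohort_products):
        series = cohort_products[0]["series"]["PIM(FMpre)"]
        profile = ap.mean_profile(series, 60)
        day = series.epoch_starts // MS_PER_DAY
        full = [d for d in np.unique(day)
                if (day == d).sum() == 1440]
        stack = np.stack([series.values[day == d] for d in full])
        assert np.allclose(profile.bins, stack.mean(axis=0))

    def test_incomplete_day_rejected(self):
        series = ap.ActivitySeries("PIM(ENMO)", 60,
                                   np.arange(100, dtype=np.int64) * 60000,
                                   np.ones(100))
        with pytest.raises(ConfigurationError):
            ap.mean_profile(series, 60)


class TestL5M10:
    def test_unique_zero_block(self):
        bins = np.full(1440, 10.0)
        bins[60:360] = 0.0  # 01:00-06:00
        l5, _ = ap.locate_l5_m10(DailyProfile(60, bins, 1))
        assert l5.onset_s == 3600
        assert l5.mean_value == 0.0

    def test_m10_block(self):
        bins = np.zeros(1440)
        bins[540:1140] = 10.0  # 09:00-19:00
        _, m10 = ap.locate_l5_m10(DailyProfile(60, bins, 1))
        assert m10.onset_s == 9 * 3600
        assert m10.mean_value == 10.0

    def test_wraps_midnight(self):
        bins = np.full(1440, 5.0)
        bins[-120:] = 0.0  # 22:00-24:00
        bins[:180] = 0.0   # 00:00-03:00
        l5, _ = ap.locate_l5_m10(DailyProfile(60, bins, 1))
        assert l5.onset_s == 22 * 3600
        assert l5.mean_value == 0.0

    def test_degenerate_flat_profile(self):
        l5, m10 = ap.locate_l5_m10(DailyProfile(60, np.full(1440, 2.0), 1))
        assert l5.onset_s == 0 and m10.onset_s == 0
        assert l5.mean_value == m10.mean_value == 2.0


class TestRelativeAmplitude:
    @pytest.mark.parametrize("m10, l5, expected",
                             [(10, 0, 1.0), (5, 5, 0.0), (3, 1, 0.5)])
    def test_values(self, m10, l5, expected):
        assert ap.relative_amplitude(m10, l5) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedValueError):
            ap.relative_amplitude(0.0, 0.0)

    def test_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            ap.relative_amplitude(1.0, 2.0)


class TestIsIv:
    def test_periodic_series_is_one(self):
        rng = np.random.default_rng(0)
        day = rng.uniform(0, 5, 24)
        x = np.tile(day, 10)
        assert ap.interdaily_stability(x) == pytest.approx(1.0, abs=1e-12)

    def test_sinusoid_iv_closed_form(self):
        """Hourly 24 h sinusoid: IV converges to 2(1 - cos(2 pi / 24))."""
        i = np.arange(24 * 50)
        x = np.sin(2 * np.pi * i / 24)
        expected = 2 * (1 - np.cos(2 * np.pi / 24))
        assert ap.intradaily_variability(x) == pytest.approx(expected,
                                                             rel=0.01)

    def test_iid_noise_limits(self):
        """White noise: IS ~ 1/D, IV ~ 2."""
        rng = np.random.default_rng(1)
        d = 100
        x = rng.normal(size=24 * d)
        assert abs(ap.interdaily_stability(x) - 1.0 / d) < 0.005
        assert ap.intradaily_variability(x) == pytest.approx(2.0, abs=0.15)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedValueError):
            ap.interdaily_stability(np.ones(48))


class TestNpcraFromSignal:
    def test_ufm_rejected_with_gravity_message(self, rec_and_truth):
        rec, _ = rec_and_truth
        with pytest.raises(ConfigurationError, match="gravitational constant"):
            ap.npcra_from_signal(ap.preprocess(rec, "UFM"))

    def test_signed_schemes_need_rectification(self, rec_and_truth):
        rec, _ = rec_and_truth
        fmpost = ap.preprocess(rec, "FMpost")
        with pytest.raises(ConfigurationError, match="rectify"):
            ap.npcra_from_signal(fmpost)
        res = ap.npcra_from_signal(ap.rectify(fmpost))
        assert 0 <= res.ra <= 1

    def test_scale_invariance(self, cohort_products):
        series = cohort_products[0]["series"]["PIM(FMpre)"]
        scaled = ap.ActivitySeries(series.method, series.epoch_length,
                                   series.epoch_starts, series.values * 7.3)
        a = ap.npcra_from_signal(series, normalize=True)
        b = ap.npcra_from_signal(scaled, normalize=True)
        assert b.l5.mean_value == pytest.approx(a.l5.mean_value, rel=1e-12)
        assert b.m10.mean_value == pytest.approx(a.m10.mean_value, rel=1e-12)
        assert b.l5.onset_s == a.l5.onset_s
        assert b.ra == pytest.approx(a.ra, rel=1e-12)
        assert b.is_ == pytest.approx(a.is_, rel=1e-12)
        assert b.iv == pytest.approx(a.iv, rel=1e-12)

    def test_result_ranges(self, cohort_products):
        for prod in cohort_products:
            for res in prod["npcra"].values():
                assert -1e-9 <= res.ra <= 1 + 1e-9
                assert -1e-9 <= res.is_ <= 1 + 1e-9
                assert -1e-9 <= res.iv <= 2 + 1e-9
                assert res.l5.mean_value <= res.m10.mean_value
                assert 0 <= res.l5.onset_s < 86400

    def test_l5_recovery_within_schedule(self, cohort_products):
        """PIM(FMpre) L5 windows fall inside the 22:30-08:00 band around
        the configured 23:30-07:00 sleep schedule for >= 95% of subjects."""
        def in_band(onset_s):
            lo, hi = 22.5 * 3600, 8.0 * 3600  # wraps midnight
            end = (onset_s + 5 * 3600) % 86400
            return (onset_s >= lo or onset_s < hi) and (end > lo or end <= hi)

        hits = [in_band(p["npcra"]["PIM(FMpre)"].l5.onset_s)
                for p in cohort_products]
        assert np.mean(hits) >= 0.95

    def test_acceleration_vs_activity_is_agreement(self, cohort_products):
        """IS from 1 s ENMO acceleration profiles agrees with IS from
        PIM(ENMO) activity (SMAPE < 5%)."""
        smapes = []
        for prod in cohort_products:
            a = prod["npcra_accel_enmo"].is_
            b = prod["npcra"]["PIM(ENMO)"].is_
            smapes.append(abs(a - b) / ((a + b) / 2) * 100)
        assert float(np.mean(smapes)) < 5.0


def test_window_designation_formatting():
    w = WindowDesignation(onset_s=3660, length_h=5, mean_value=1.0)
    assert w.onset_hhmm == "01:01"
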