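"""Unit behaviour of the 16 quality features on analytic signals."""

import numpy as np
import pytest

from fecgsqa import Segment, compute_sqi_vector
from fecgsqa.sqi import (
    FEATURE_NAMES,
    amplitude_stats,
    band_power,
    band_power_integrated,
    baseline_std,
    estimate_psd,
    hjorth_complexity,
    moments,
    power_ratios,
    spectral_entropy,
    steepest_slope,
)
from fecgsqa.synthgen import FETAL_TEMPLATE, ecg_waveform

FS = 500.0
N = 2500


def seg(x):
    return Segment(np.asarray(x, dtype=float), FS)


def sine(f, amp=1.0, fs=FS, n=N):
    return amp * np.sin(2 * np.pi * f * np.arange(n) / fs)


class TestPSD:
    def test_tone_lands_in_its_bin(self):
        psd = estimate_psd(seg(sine(15)))
        assert abs(psd.freqs[np.argmax(psd.power)] - 15.0) <= 1.0

    def test_zeros_give_zero_psd(self):
        psd = estimate_psd(seg(np.zeros(N)))
        assert np.all(psd.power == 0)

    def test_white_noise_total_power_matches_variance(self):
        ratios = []
        for s in range(50):
            x = np.random.default_rng(s).standard_normal(N) * 3.0
            psd = estimate_psd(seg(x))
            df = psd.freqs[1] - psd.freqs[0]
            ratios.append(np.sum(psd.power) * df / np.var(x))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


class TestBandPower:
    def test_tone_power_concentrated_in_band(self):
        psd = estimate_psd(seg(sine(15)))
        assert band_power(psd, 10, 20) > 100 * band_power(psd, 52, 100)

    def test_flat_psd_mean_is_the_level(self):
        psd = estimate_psd(seg(np.zeros(N)))
        psd.power = np.full_like(psd.power, 7.0)
        assert band_power(psd, 10, 20) == pytest.approx(7.0)
        assert band_power(psd, 0.5, 10) == pytest.approx(7.0)

    def test_zeros_band_power_zero(self):
        psd = estimate_psd(seg(np.zeros(N)))
        assert band_power(psd, 0.5, 10) == 0.0


class TestSpectralEntropy:
    def test_single_bin_minimal(self):
        psd = estimate_psd(seg(np.zeros(N)))
        psd.power = np.zeros_like(psd.power)
        psd.power[40] = 5.0
        assert spectral_entropy(psd) == 0.0

    def test_flat_maximal(self):
        psd = estimate_psd(seg(np.zeros(N)))
        psd.power = np.ones_like(psd.power)
        assert spectral_entropy(psd) == pytest.approx(1.0)

    def test_white_noise_high(self):
        values = [
            spectral_entropy(estimate_psd(seg(
                np.random.default_rng(s).standard_normal(N))))
            for s in range(20)
        ]
        assert np.mean(values) > 0.9

    def test_all_zero_psd_defined_as_zero(self):
        assert spectral_entropy(estimate_psd(seg(np.zeros(N)))) == 0.0


class TestBaselineStd:
    def test_constant_baseline_has_zero_std(self):
        assert baseline_std(seg(np.full(N, 5.0))) == pytest.approx(0.0, abs=1e-12)

    def test_slow_drift_passes_the_average(self):
        a = 10.0
        value = baseline_std(seg(sine(0.2, amp=a)))
        assert value == pytest.approx(a / np.sqrt(2), rel=0.15)

    def test_fast_tone_is_averaged_out(self):
        a = 10.0
        assert baseline_std(seg(sine(50, amp=a))) < 0.02 * a / np.sqrt(2)


class TestSlopeAndAmplitudes:
    def test_ramp_slope(self):
        ramp = np.arange(N) * 2.0
        assert steepest_slope(seg(ramp)) == pytest.approx(1000.0)

    def test_constant_slope_zero(self):
        assert steepest_slope(seg(np.full(N, 3.0))) == 0.0

    def test_sine_slope_matches_derivative_bound(self):
        assert steepest_slope(seg(sine(10))) == pytest.approx(
            2 * np.pi * 10, rel=0.05
        )

    def test_signed_extremes(self):
        ha, la, _ = amplitude_stats(seg(np.r_[[-3.0, 0.0, 5.0], np.zeros(N - 3)]))
        assert (ha, la) == (5.0, -3.0)

    def test_constant_stats(self):
        ha, la, std = amplitude_stats(seg(np.full(N, 2.0)))
        assert (ha, la, std) == (2.0, 2.0, 0.0)

    def test_unit_sine_std(self):
        _, _, std = amplitude_stats(seg(sine(10)))  # full periods
        assert std == pytest.approx(1 / np.sqrt(2), rel=0.01)


class TestMoments:
    @pytest.mark.parametrize("s", [0, 1, 2])
    def test_gaussian_reference_values(self, s):
        x = np.random.default_rng(s).standard_normal(N)
        k, skewness, deg = moments(seg(x))
        assert not deg
        assert k == pytest.approx(3.0, abs=0.3)
        assert skewness == pytest.approx(0.0, abs=0.15)

    def test_symmetric_two_point_signal(self):
        x = np.tile([1.0, -1.0], N // 2)
        k, s, _ = moments(seg(x))
        assert s == pytest.approx(0.0, abs=1e-12)
        assert k == pytest.approx(1.0)

    def test_spike_train_is_leptokurtic(self):
        x, _ = ecg_waveform(140, FS, 5.0, 10.0, seed=0, template=FETAL_TEMPLATE)
        k, _, _ = moments(seg(x))
        assert k > 5.0

    def test_constant_flags_degenerate(self):
        k, s, deg = moments(seg(np.full(N, 4.0)))
        assert deg and k == 0.0 and s == 0.0


class TestPowerRatios:
    def test_qrs_band_tone(self):
        psqi, _, _ = power_ratios(estimate_psd(seg(sine(10))))
        assert psqi >= 0.99

    def test_tone_outside_numerator_band(self):
        psqi, _, _ = power_ratios(estimate_psd(seg(sine(30))))
        assert psqi <= 0.01

    def test_baseline_tone_dominates_basqi(self):
        _, basqi, _ = power_ratios(estimate_psd(seg(sine(1.5))))
        assert basqi >= 0.99

    def test_integrated_band_truncates_at_nyquist(self):
        psd = estimate_psd(seg(sine(10)))
        full = band_power_integrated(psd, 0.0, 100.0)
        assert full > 0


class TestHjorth:
    @pytest.mark.parametrize("f", [2, 10, 40])
    def test_pure_tone_scores_one(self, f):
        c, deg = hjorth_complexity(seg(sine(f)))
        assert not deg
        assert c == pytest.approx(1.0, abs=0.02)

    def test_white_noise_above_tone(self):
        values = [
            hjorth_complexity(seg(np.random.default_rng(s).standard_normal(N)))[0]
            for s in range(50)
        ]
        assert min(values) > 1.2

    def test_two_tone_mixture_exceeds_each_tone(self):
        mix, _ = hjorth_complexity(seg(sine(5) + sine(45)))
        lo, _ = hjorth_complexity(seg(sine(5)))
        hi, _ = hjorth_complexity(seg(sine(45)))
        assert mix > lo and mix > hi


class TestSQIVector:
    def test_zeros_degenerate(self):
        v = compute_sqi_vector(seg(np.zeros(N)))
        assert v.degenerate
        assert np.all(v.to_array() == 0.0)

    def test_feature_order_is_relevance_rank_order(self):
        assert FEATURE_NAMES == (
            "pband2", "seSQI", "pband4", "bas_pow", "pband3", "ss", "pband1",
            "HA", "stdSQI", "kSQI", "pband5", "LA", "pSQI", "complexity",
            "basSQI", "sSQI",
        )
        v = compute_sqi_vector(seg(sine(10)))
        assert list(v.to_dict()) == list(FEATURE_NAMES)

    def test_informative_channel_profile(self, small_recording):
        from fecgsqa.preprocess import TRAIN_PRESET, preprocess_recording, segment_channel

        rec, _ = small_recording
        pre = preprocess_recording(rec, TRAIN_PRESET)
        v = compute_sqi_vector(segment_channel(pre.samples[0], pre.fs)[1])
        assert v.kSQI > 3.0
        assert v.pband2 > v.pband5

    def test_scale_covariance(self):
        rng = np.random.default_rng(7)
        x, _ = ecg_waveform(140, FS, 5.0, 8.0, seed=3, template=FETAL_TEMPLATE)
        x = x + rng.standard_normal(N)
        c = 3.7
        a = compute_sqi_vector(seg(x))
        b = compute_sqi_vector(seg(c * x))
        linear = ("HA", "LA", "stdSQI", "bas_pow", "ss")
        quadratic = ("pband1", "pband2", "pband3", "pband4", "pband5")
        invariant = ("seSQI", "kSQI", "sSQI", "pSQI", "basSQI", "complexity")
        for name in linear:
            assert getattr(b, name) == pytest.approx(c * getattr(a, name), rel=1e-9)
        for name in quadratic:
            assert getattr(b, name) == pytest.approx(c**2 * getattr(a, name), rel=1e-9)
        for name in invariant:
            assert getattr(b, name) == pytest.approx(getattr(a, name), rel=1e-9)
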