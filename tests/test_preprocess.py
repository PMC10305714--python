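import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driveact.preprocess import (
    CHANNEL_NAMES,
    ModelInput,
    PreprocConfig,
    acc_clean,
    detrend_diff,
    lowpass_zerophase,
    median_stage,
    preprocess_recording,
    resample_to_length,
    samples_to_seconds,
    seconds_to_samples,
    sliding_windows,
    synchronize,
    zscore,
)
from driveact.synthetic import SyntheticConfig, synthesize_recording


def butterworth_squared_magnitude(f: float, cutoff: float, order: int = 2) -> float:
    """Independent closed-form oracle: |H(f)|^2 of an analog Butterworth,
    which is the effective gain of the forward-backward filter."""
    return 1.0 / (1.0 + (f / cutoff) ** (2 * order))


class TestLowpassZerophase:
    def test_constant_passthrough(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass_zerophase(x, 20.0, 200.0), x, atol=1e-9)

    def test_passband_sine_amplitude_and_zero_lag(self):
        rate, f = 200.0, 2.0
        t = np.arange(4000) / rate
        x = np.sin(2 * np.pi * f * t)
        y = lowpass_zerophase(x, 20.0, rate)
        core = slice(500, -500)
        assert np.max(np.abs(y[core])) >= 0.99
        # zero-phase: cross-correlation peaks at lag 0
        lags = range(-20, 21)
        xc = [np.dot(y[500:-500], x[500 + lag : len(x) - 500 + lag]) for lag in lags]
        assert list(lags)[int(np.argmax(xc))] == 0

    def test_stopband_attenuation_matches_squared_butterworth(self):
        rate, f, cutoff = 200.0, 45.0, 20.0
        t = np.arange(8000) / rate
        x = np.sin(2 * np.pi * f * t)
        y = lowpass_zerophase(x, cutoff, rate)
        amp = np.max(np.abs(y[1000:-1000]))
        bound = butterworth_squared_magnitude(f, cutoff) + 0.01
        assert amp <= bound

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_zerophase(np.zeros(100), 120.0, 200.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            lowpass_zerophase(np.zeros(5), 20.0, 200.0)


class TestDetrendDiff:
    def test_constant_to_zeros(self):
        np.testing.assert_array_equal(detrend_diff(np.full(10, 4.2)), np.zeros(10))

    def test_ramp_to_constant(self):
        x = 0.5 * np.arange(20)
        np.testing.assert_allclose(detrend_diff(x), np.full(20, 0.5))

    def test_hand_evaluated_example(self):
        np.testing.assert_array_equal(detrend_diff([1.0, 3.0, 2.0]), [2.0, 2.0, -1.0])

    def test_length_preserved(self):
        assert len(detrend_diff(np.arange(57.0))) == 57

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detrend_diff([1.0])


def brute_force_median(x, kernel):
    half = kernel // 2
    out = np.empty(len(x))
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        window = list(x[lo:hi])
        # edge-replicate to full kernel
        window += [x[0]] * (half - i) if i < half else []
        window += [x[-1]] * (i + half + 1 - len(x)) if i + half + 1 > len(x) else []
        out[i] = np.median(window)
    return out


class TestAccClean:
    def test_median_stage_removes_single_spike_kernel3(self):
        x = np.array([1.0, 1.0, 9.0, 1.0, 1.0])
        np.testing.assert_array_equal(median_stage(x, 3), np.ones(5))

    def test_median_stage_removes_impulse_kernel5(self):
        x = np.zeros(50)
        x[25] = 100.0
        np.testing.assert_array_equal(median_stage(x, 5), np.zeros(50))

    def test_median_stage_matches_brute_force(self, rng):
        x = rng.normal(size=200)
        for kernel in (3, 5, 7):
            np.testing.assert_allclose(median_stage(x, kernel), brute_force_median(x, kernel))

    def test_constant_unchanged(self):
        x = np.full(100, 2.5)
        np.testing.assert_allclose(acc_clean(x), x, atol=1e-6)

    def test_impulse_suppressed_end_to_end(self):
        x = np.zeros(200)
        x[100] = 50.0
        y = acc_clean(x)
        assert np.max(np.abs(y)) < 1e-6

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            acc_clean(np.zeros(10))


class TestZscore:
    def test_derived_example(self):
        np.testing.assert_allclose(
            zscore([2.0, 4.0, 6.0]), [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_mean_zero_sd_one(self, rng):
        x = rng.normal(3.0, 7.0, size=1000)
        z = zscore(x)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_constant_gives_zeros(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="driveact.preprocess"):
            z = zscore([5.0, 5.0, 5.0])
        np.testing.assert_array_equal(z, np.zeros(3))
        assert any("constant" in rec.message for rec in caplog.records)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.array([]))

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, values):
        x = np.asarray(values)
        z = zscore(x)
        np.testing.assert_allclose(zscore(z) if z.std() > 0 else z, z, atol=1e-9)


def brute_force_windows(n, window_len, stride):
    """Independent enumeration of window starts under the truncation rule."""
    truncated = (n // stride) * stride
    return [s for s in range(0, truncated + 1, stride) if s + window_len <= truncated]


class TestSlidingWindows:
    def test_exact_window_length(self):
        assert len(sliding_windows(np.zeros(280), 280, 140)) == 1

    def test_length_420_two_windows(self):
        wins = sliding_windows(np.arange(420), 280, 140)
        assert len(wins) == 2
        assert wins[0][0] == 0 and wins[1][0] == 140

    def test_length_279_truncates_to_zero_windows(self):
        assert sliding_windows(np.zeros(279), 280, 140) == []

    def test_matches_brute_force_for_all_lengths(self):
        for n in range(0, 1001):
            got = len(sliding_windows(np.zeros(n), 280, 140))
            assert got == len(brute_force_windows(n, 280, 140)), n

    @given(
        n=st.integers(0, 500),
        window=st.integers(1, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_random_geometry(self, n, window):
        stride = max(1, window // 2)
        got = sliding_windows(np.zeros(n), window, stride)
        expected = brute_force_windows(n, window, stride)
        assert len(got) == len(expected)

    def test_multichannel_windows(self):
        wins = sliding_windows(np.zeros((420, 7)), 280, 140)
        assert all(w.shape == (280, 7) for w in wins)


class TestResample:
    def test_identity_length(self, rng):
        x = rng.normal(size=(3000, 2))
        np.testing.assert_allclose(resample_to_length(x, 3000), x, atol=1e-9)

    def test_linear_ramp(self):
        x = np.linspace(0.0, 1.0, 101)
        y = resample_to_length(x, 3000)
        np.testing.assert_allclose(y, np.linspace(0.0, 1.0, 3000), atol=1e-6)

    def test_constant(self):
        y = resample_to_length(np.full(50, 2.2), 3000)
        np.testing.assert_allclose(y, 2.2)

    def test_endpoints_preserved(self, rng):
        x = rng.normal(size=77)
        y = resample_to_length(x, 600)
        assert y[0] == pytest.approx(x[0])
        assert y[-1] == pytest.approx(x[-1])

    def test_monotone_preserved(self):
        x = np.sort(np.random.default_rng(0).normal(size=40))
        y = resample_to_length(x, 200)
        assert np.all(np.diff(y) >= -1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            resample_to_length(np.ones(1), 100)


class TestSynchronize:
    def test_shortest_recording_103_samples(self):
        rec = synthesize_recording(15, 2.06, seed=0)
        synced = synchronize(rec)
        assert synced.shape == (103, 7)

    def test_longest_recording_3013_samples(self):
        rec = synthesize_recording(9, 60.26, seed=0)
        assert synchronize(rec).shape == (3013, 7)

    def test_non_integer_factor_rejected(self, sample_recording):
        with pytest.raises(ValueError):
            synchronize(sample_recording, sync_rate_Hz=60.0)

    def test_factor_one_unchanged_channel(self, sample_recording):
        # ACC at 100 Hz synchronized to 100 Hz is a pure passthrough
        synced = synchronize(sample_recording, sync_rate_Hz=100.0)
        np.testing.assert_array_equal(synced[: len(sample_recording.acc_x), 0], sample_recording.acc_x)

    def test_duration_accounting(self):
        assert samples_to_seconds(3013, 50.0) == pytest.approx(60.26)
        assert samples_to_seconds(103, 50.0) == pytest.approx(2.06)
        assert seconds_to_samples(5.6, 50.0) == 280


class TestPreprocessRecording:
    def test_whole_resampled_shape_and_normalization(self, sample_recording):
        cfg = PreprocConfig(model_input_len=3000)
        out = preprocess_recording(sample_recording, cfg)
        assert isinstance(out, ModelInput)
        assert out.values.shape == (3000, 7)
        assert np.all(np.isfinite(out.values))
        means = out.values.mean(axis=0)
        sds = out.values.std(axis=0)
        np.testing.assert_allclose(means, 0.0, atol=1e-6)
        np.testing.assert_allclose(sds, 1.0, atol=1e-6)

    def test_longest_recording_one_input(self):
        rec = synthesize_recording(9, 60.26, seed=1)
        out = preprocess_recording(rec, PreprocConfig(model_input_len=3000))
        assert out.values.shape == (3000, 7)

    def test_window_mode_5p6s_gives_one_window(self):
        rec = synthesize_recording(2, 5.6, seed=1)
        cfg = PreprocConfig(segmentation_mode="windows")
        wins = preprocess_recording(rec, cfg)
        assert isinstance(wins, list)
        assert len(wins) == 1
        assert wins[0].values.shape == (280, 7)

    def test_deterministic(self, sample_recording):
        cfg = PreprocConfig(model_input_len=600)
        a = preprocess_recording(sample_recording, cfg)
        b = preprocess_recording(sample_recording, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_stage_failure_names_stage(self):
        rec = synthesize_recording(0, 2.06, SyntheticConfig(duration_range_s=(2.06, 3.0)), seed=0)
        # 103 synced samples cannot fill a 280-sample window: windows mode gives []
        cfg = PreprocConfig(segmentation_mode="windows")
        assert preprocess_recording(rec, cfg) == []

    def test_label_carried_through(self, sample_recording):
        out = preprocess_recording(sample_recording, PreprocConfig(model_input_len=600))
        assert out.label == sample_recording.label


class TestPreprocConfig:
    def test_window_arithmetic(self):
        cfg = PreprocConfig()
        assert cfg.window_len_samples == 280
        assert cfg.stride_samples == 140

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            PreprocConfig(acc_median_kernel=4)

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            PreprocConfig(eog_lowpass_cutoff_Hz=150.0)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            PreprocConfig(segmentation_mode="chunks")
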