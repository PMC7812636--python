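"""Filters, QRS detection, RR cleaning, epoching, artifact marking, tonic SCL."""

import numpy as np
import pytest

from dyadflow import preprocessing as pre
from dyadflow.preprocessing import RrSeries


def sine(freq, fs, seconds, amp=1.0, phase=0.0):
    t = np.arange(int(fs * seconds)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestFilters:
    def test_bandpass_passes_band_and_rejects_outside(self):
        fs = 256.0
        inside = sine(10.0, fs, 20)
        outside = sine(60.0, fs, 20)
        y_in = pre.butter_bandpass(inside, fs, 1.0, 35.0)
        y_out = pre.butter_bandpass(outside, fs, 1.0, 35.0)
        mid = slice(1000, -1000)  # ignore filter edges
        assert np.std(y_in[mid]) > 0.9 * np.std(inside[mid])
        assert np.std(y_out[mid]) < 0.05 * np.std(outside[mid])

    def test_bandpass_zero_phase(self):
        fs = 256.0
        x = sine(8.0, fs, 20)
        y = pre.butter_bandpass(x, fs, 1.0, 35.0)
        mid = slice(1000, -1000)
        # zero-phase filtering keeps the passband sine aligned
        assert np.corrcoef(x[mid], y[mid])[0, 1] > 0.999

    def test_bandpass_bad_edges(self):
        with pytest.raises(ValueError):
            pre.butter_bandpass(np.zeros(100), 256.0, 40.0, 35.0)
        with pytest.raises(ValueError):
            pre.butter_bandpass(np.zeros(100), 256.0, 1.0, 200.0)

    def test_notch_removes_50hz(self):
        fs = 256.0
        x = sine(50.0, fs, 20) + sine(10.0, fs, 20)
        y = pre.notch50(x, fs)
        mid = slice(1000, -1000)
        # the 10 Hz component survives, the 50 Hz mains line does not
        freqs = np.fft.rfftfreq(y[mid].size, 1 / fs)
        spec = np.abs(np.fft.rfft(y[mid]))
        i50 = np.argmin(np.abs(freqs - 50.0))
        i10 = np.argmin(np.abs(freqs - 10.0))
        assert spec[i50] < 0.05 * spec[i10]

    def test_notch_needs_headroom(self):
        with pytest.raises(ValueError):
            pre.notch50(np.zeros(100), 80.0)

    def test_multichannel_matches_per_channel(self, rng):
        fs = 256.0
        x = rng.standard_normal((2560, 3))
        y = pre.butter_bandpass(x, fs, 1.0, 35.0)
        for k in range(3):
            yk = pre.butter_bandpass(x[:, k], fs, 1.0, 35.0)
            assert np.allclose(y[:, k], yk, atol=1e-10)


def synth_ecg(rr_intervals, fs=256.0, noise=0.0, seed=0):
    """Impulse-like beats at the cumulated RR times (test oracle signal)."""
    beat_times = np.concatenate([[0.5], 0.5 + np.cumsum(rr_intervals)])
    n = int((beat_times[-1] + 0.5) * fs)
    t = np.arange(n) / fs
    ecg = np.zeros(n)
    for bt in beat_times:
        ecg += np.exp(-((t - bt) ** 2) / (2 * 0.008**2))
    rng = np.random.default_rng(seed)
    return ecg + noise * rng.standard_normal(n), beat_times


class TestPanTompkins:
    def test_recovers_known_beat_times(self):
        rr = np.full(60, 0.8)
        ecg, truth = synth_ecg(rr, noise=0.02)
        filtered = pre.butter_bandpass(ecg, 256.0, 5.0, 20.0)
        series = pre.pan_tompkins_rpeaks(filtered, 256.0)
        assert abs(series.beat_times.size - truth.size) <= 1
        # match detected beats to the nearest true beats
        det = series.beat_times
        err = np.array([np.min(np.abs(truth - d)) for d in det])
        assert np.max(err) < 0.03

    def test_irregular_rhythm(self, rng):
        rr = rng.uniform(0.6, 1.1, size=80)
        ecg, truth = synth_ecg(rr, noise=0.02, seed=1)
        filtered = pre.butter_bandpass(ecg, 256.0, 5.0, 20.0)
        series = pre.pan_tompkins_rpeaks(filtered, 256.0)
        assert abs(series.rr.size - rr.size) <= 2
        assert abs(np.mean(series.rr) - np.mean(rr)) < 0.02

    def test_too_short(self):
        with pytest.raises(ValueError, match="5 s"):
            pre.pan_tompkins_rpeaks(np.zeros(100), 256.0)

    def test_flat_signal(self):
        with pytest.raises(ValueError, match="flat"):
            pre.pan_tompkins_rpeaks(np.zeros(2560), 256.0)


class TestCleanEctopicRr:
    def test_single_ectopic_replaced(self):
        rr = np.full(50, 0.8)
        rr[20] = 1.4  # > 25% off the local median
        series = RrSeries(beat_times=np.concatenate([[0.0], np.cumsum(rr)]), rr=rr)
        cleaned = pre.clean_ectopic_rr(series)
        assert cleaned.n_replaced == 1
        assert abs(cleaned.rr[20] - 0.8) < 0.05
        assert np.allclose(np.delete(cleaned.rr, 20), 0.8)

    def test_out_of_range_replaced(self):
        rr = np.full(40, 0.9)
        rr[5] = 2.5
        rr[30] = 0.1
        series = RrSeries(beat_times=np.concatenate([[0.0], np.cumsum(rr)]), rr=rr)
        cleaned = pre.clean_ectopic_rr(series)
        assert cleaned.n_replaced == 2
        assert np.all((cleaned.rr >= 0.3) & (cleaned.rr <= 2.0))

    def test_too_many_ectopics_is_unusable(self, rng):
        rr = np.where(rng.random(40) < 0.5, 0.4, 1.6)
        series = RrSeries(beat_times=np.concatenate([[0.0], np.cumsum(rr)]), rr=rr)
        with pytest.raises(ValueError, match="unusable"):
            pre.clean_ectopic_rr(series)

    def test_beat_times_stay_consistent(self):
        rr = np.full(30, 0.8)
        rr[10] = 1.3
        series = RrSeries(beat_times=np.concatenate([[5.0], 5.0 + np.cumsum(rr)]), rr=rr)
        cleaned = pre.clean_ectopic_rr(series)
        assert cleaned.beat_times[0] == 5.0
        assert np.allclose(np.diff(cleaned.beat_times), cleaned.rr)


class TestEpoching:
    def test_shapes_and_partial_second_dropped(self):
        fs = 256.0
        data = np.arange(int(10.5 * fs))[:, None].astype(float)
        epochs = pre.epoch_signal(data, fs, ["ch"])
        assert epochs.data.shape == (10, 1, 256)
        # each epoch holds the half-open second [k, k+1)
        assert epochs.data[3, 0, 0] == 3 * 256

    def test_too_short(self):
        with pytest.raises(ValueError):
            pre.epoch_signal(np.zeros((100, 1)), 256.0, ["ch"])


class TestArtifactRejection:
    def _epochs(self, data, fs=256.0):
        return pre.epoch_signal(data, fs, [f"c{i}" for i in range(data.shape[1])])

    def test_amplitude_criterion(self):
        fs = 256.0
        data = np.zeros((int(3 * fs), 2)) + np.sin(np.arange(int(3 * fs)))[:, None]
        data[400, 0] = 150.0  # epoch 1, channel 0
        out = pre.reject_artifacts(self._epochs(data, fs))
        assert out.rejected[1, 0]
        assert not out.rejected[1, 1]
        assert np.isnan(out.data[1, 0]).all()

    def test_slope_criterion(self):
        fs = 256.0
        t = np.arange(int(3 * fs)) / fs
        data = np.zeros((t.size, 2))
        data[:, 0] = 20.0 * t  # 20 uV/s drift, amplitude stays < 100
        out = pre.reject_artifacts(self._epochs(data, fs))
        assert out.rejected[:, 0].all()
        assert not out.rejected[:, 1].any()

    def test_step_criterion(self):
        fs = 256.0
        data = np.zeros((int(3 * fs), 1))
        data[500:, 0] = 30.0  # a 30 uV jump inside epoch 1
        out = pre.reject_artifacts(self._epochs(data, fs))
        assert out.rejected[1, 0]
        assert not out.rejected[0, 0]

    def test_clean_data_untouched(self, rng):
        fs = 256.0
        # small iid noise: successive-sample steps stay far below 25 uV
        data = 2.0 * rng.standard_normal((int(5 * fs), 3))
        out = pre.reject_artifacts(self._epochs(data, fs))
        assert not out.rejected.any()
        assert out.rejected_fraction == 0.0


class TestTonicScl:
    def test_recovers_slow_trend_under_phasic_bumps(self):
        fs = 64.0
        t = np.arange(int(fs * 120)) / fs
        tonic = 5.0 + 0.5 * np.sin(2 * np.pi * t / 60.0)
        eda = tonic.copy()
        for onset in (20.0, 50.0, 80.0):  # sparse SCR-like positive bumps
            dt = t - onset
            eda += np.where(dt > 0, 0.4 * (1 - np.exp(-dt / 0.75)) * np.exp(-dt / 3.0), 0.0)
        scl = pre.extract_tonic_scl(eda, fs)
        mid = slice(10 * 16, -10 * 16)
        t16 = np.arange(scl.values.size) / 16.0
        truth = 5.0 + 0.5 * np.sin(2 * np.pi * t16 / 60.0)
        # 0.4 uS bumps leak at most ~0.11 uS through the 10 s median window
        assert np.max(np.abs(scl.values[mid] - truth[mid])) < 0.15
        assert np.corrcoef(scl.values[mid], truth[mid])[0, 1] > 0.98

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            pre.extract_tonic_scl(np.full(640, -1.0), 64.0)

    def test_rate_must_be_multiple_of_16(self):
        with pytest.raises(ValueError):
            pre.extract_tonic_scl(np.ones(600), 60.0)
        with pytest.raises(ValueError):
            pre.extract_tonic_scl(np.ones(600), 8.0)

    def test_output_rate(self):
        scl = pre.extract_tonic_scl(np.ones(6400), 64.0)
        assert scl.fs == 16.0
        assert scl.values.size == 1600


class TestBaselineNormalize:
    def _scl(self):
        times = np.arange(0, 120, 1 / 16)
        values = np.full(times.size, 4.0)
        values[times >= 60] = 6.0
        return pre.SclSeries(times=times, values=values, fs=16.0)

    def test_subtractive(self):
        out = pre.baseline_normalize_scl(self._scl(), (0.0, 60.0))
        assert np.allclose(out.values[out.times < 60], 0.0)
        assert np.allclose(out.values[out.times >= 60], 2.0)

    def test_divisive(self):
        out = pre.baseline_normalize_scl(self._scl(), (0.0, 60.0), divide=True)
        assert np.allclose(out.values[out.times >= 60], 1.5)

    def test_interval_outside_recording(self):
        with pytest.raises(ValueError):
            pre.baseline_normalize_scl(self._scl(), (500.0, 600.0))
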