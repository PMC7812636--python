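"""Signal conditioning for the three modalities.

ECG: 5-20 Hz 5th-order Butterworth band-pass, Pan-Tompkins R-peak detection,
ectopic interbeat-interval cleaning.  EEG: 1-35 Hz band-pass, 50 Hz notch,
1-s epoching and three-criterion artifact marking (amplitude, slope,
sample-to-sample step).  EDA: downsampling to 16 Hz and a percentile-based
tonic skin-conductance-level extraction with baseline normalization.

All filtering is zero-phase (forward-backward), so no stage introduces a
group delay between modalities that must stay synchronized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import CubicSpline

__all__ = [
    "RrSeries",
    "EpochArray",
    "SclSeries",
    "butter_bandpass",
    "notch50",
    "pan_tompkins_rpeaks",
    "clean_ectopic_rr",
    "epoch_signal",
    "reject_artifacts",
    "eyeblink_regress",
    "extract_tonic_scl",
    "baseline_normalize_scl",
]


@dataclass
class RrSeries:
    """Interbeat intervals: rr[i] spans beat_times[i] -> beat_times[i+1]."""

    beat_times: np.ndarray  # seconds, ascending, length n+1
    rr: np.ndarray  # seconds, length n
    n_replaced: int = 0

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.beat_times.size != self.rr.size + 1:
            raise ValueError("beat_times must be one longer than rr")
        if np.any(self.rr <= 0):
            raise ValueError("interbeat intervals must be positive")
        if not np.allclose(np.diff(self.beat_times), self.rr, atol=1e-9):
            raise ValueError("rr must equal successive beat-time differences")

    @property
    def midpoints(self) -> np.ndarray:
        """Time stamps used when resampling the tachogram."""
        return 0.5 * (self.beat_times[:-1] + self.beat_times[1:])


@dataclass
class EpochArray:
    """1-s EEG epochs with a per-(epoch, channel) rejection mask."""

    data: np.ndarray  # (n_epochs, n_channels, n_samples) in microvolts
    fs: float
    channel_names: list[str]
    rejected: np.ndarray | None = None  # (n_epochs, n_channels) boolean

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch tensor must be 3-D")
        if self.data.shape[2] != int(round(self.fs)):
            raise ValueError("samples per epoch must equal the sampling rate")
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[:2], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def rejected_fraction(self) -> float:
        return float(np.mean(self.rejected))


@dataclass
class SclSeries:
    """Tonic skin conductance level at a uniform 16 Hz grid."""

    times: np.ndarray  # seconds
    values: np.ndarray  # microsiemens
    fs: float = 16.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tonic SCL must be finite")


def butter_bandpass(x: np.ndarray, fs: float, low_hz: float, high_hz: float, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the first axis."""
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError("band edges must satisfy 0 < low < high < fs/2")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return _sosfiltfilt_axis0(sos, _as_float(x))


def notch50(x: np.ndarray, fs: float, q: float = 30.0) -> np.ndarray:
    """Zero-phase 50 Hz notch (mains interference)."""
    if fs <= 100:
        raise ValueError("sampling rate too low to notch 50 Hz")
    b, a = signal.iirnotch(50.0, q, fs=fs)
    return _sosfiltfilt_axis0(signal.tf2sos(b, a), _as_float(x))


def _as_float(x: np.ndarray) -> np.ndarray:
    """Promote to floating point, keeping single precision if given."""
    x = np.asarray(x)
    return x if x.dtype in (np.float32, np.float64) else x.astype(float)


def _sosfiltfilt_axis0(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    """sosfiltfilt along axis 0, run on a contiguous last-axis layout.

    Filtering the transposed copy avoids the stride-copy scipy makes for
    every non-contiguous multichannel call, which dominates run time on
    long recordings.  Single-precision input stays single precision, which
    roughly triples throughput on multichannel EEG.
    """
    if x.dtype == np.float32:
        sos = sos.astype(np.float32)
    if x.ndim == 1:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfiltfilt(sos, np.ascontiguousarray(x.T), axis=-1).T


def pan_tompkins_rpeaks(ecg: np.ndarray, fs: float) -> RrSeries:
    """QRS detection: derivative -> squaring -> moving-window integration ->
    adaptive dual threshold with search-back, 200 ms refractory period.

    Expects an ECG already band-passed to the QRS band (5-20 Hz).
    """
    ecg = np.asarray(ecg, dtype=float).ravel()
    if ecg.size < 5 * fs:
        raise ValueError("need at least 5 s of ECG")
    if np.ptp(ecg) < 1e-12:
        raise ValueError("no beats: flat ECG signal")

    # five-point derivative (classic Pan-Tompkins kernel), squaring, MWI 150 ms
    kernel = np.array([1, 2, 0, -2, -1]) * fs / 8.0
    deriv = np.convolve(ecg, kernel[::-1], mode="same")
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    # candidate peaks of the integrated signal
    min_dist = int(round(0.2 * fs))  # refractory period
    peaks, _ = signal.find_peaks(mwi, distance=min_dist)
    if peaks.size == 0:
        raise ValueError("no beats detected")

    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5  # running signal-peak level
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5  # running noise-peak level
    beats: list[int] = []
    missed_buffer: list[int] = []
    rr_avg = None
    for idx in peaks:
        threshold = npki + 0.25 * (spki - npki)
        if mwi[idx] > threshold:
            if beats and rr_avg is not None and (idx - beats[-1]) > 1.66 * rr_avg:
                # search-back: accept the largest skipped candidate above half threshold
                back = [j for j in missed_buffer if beats[-1] + min_dist < j < idx - min_dist]
                if back:
                    best = max(back, key=lambda j: mwi[j])
                    if mwi[best] > 0.5 * threshold:
                        beats.append(best)
                        spki = 0.25 * mwi[best] + 0.75 * spki
            beats.append(idx)
            spki = 0.125 * mwi[idx] + 0.875 * spki
            missed_buffer = []
            if len(beats) >= 2:
                rr_new = beats[-1] - beats[-2]
                rr_avg = rr_new if rr_avg is None else 0.125 * rr_new + 0.875 * rr_avg
        else:
            npki = 0.125 * mwi[idx] + 0.875 * npki
            missed_buffer.append(idx)

    if len(beats) < 2:
        raise ValueError("no beats detected")
    # refine: the MWI peak has a plateau; place the beat on the R wave itself,
    # the largest |ECG| excursion within +-75 ms of the integrated peak
    half = int(round(0.075 * fs))
    refined = []
    for idx in beats:
        lo, hi = max(0, idx - half), min(ecg.size, idx + half + 1)
        refined.append(lo + int(np.argmax(np.abs(ecg[lo:hi]))))
    beats = sorted(set(refined))
    beat_times = np.asarray(beats, dtype=float) / fs
    rr = np.diff(beat_times)
    return RrSeries(beat_times=beat_times, rr=rr)


def clean_ectopic_rr(series: RrSeries, max_fraction: float = 0.20) -> RrSeries:
    """Replace ectopic interbeat intervals by local cubic-spline interpolation.

    An interval is ectopic when it deviates more than 25% from the median of
    the 5 surrounding intervals or falls outside the physiologic range
    [0.3, 2.0] s.  More than ``max_fraction`` ectopic intervals marks the
    recording unusable.
    """
    rr = series.rr.copy()
    n = rr.size
    med = ndimage.median_filter(rr, size=5, mode="nearest")
    bad = (np.abs(rr - med) > 0.25 * med) | (rr < 0.3) | (rr > 2.0)
    if bad.mean() > max_fraction:
        raise ValueError(
            f"{bad.sum()}/{n} ectopic intervals (> {max_fraction:.0%}): recording unusable"
        )
    if bad.any():
        good = np.flatnonzero(~bad)
        if good.size < 4:
            raise ValueError("too few valid intervals to interpolate")
        spline = CubicSpline(good.astype(float), rr[good])
        idx = np.flatnonzero(bad).astype(float)
        rr[bad] = np.clip(spline(idx), 0.3, 2.0)
    beat_times = np.concatenate([[series.beat_times[0]], series.beat_times[0] + np.cumsum(rr)])
    return RrSeries(beat_times=beat_times, rr=rr, n_replaced=int(bad.sum()))


def epoch_signal(data: np.ndarray, fs: float, channel_names: list[str]) -> EpochArray:
    """Cut a (samples, channels) EEG matrix into 1-s epochs.

    Windows are half-open [k, k+1) seconds; a trailing partial second is
    dropped.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    spe = int(round(fs))
    n_epochs = data.shape[0] // spe
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    cut = data[: n_epochs * spe]
    tensor = cut.reshape(n_epochs, spe, data.shape[1]).transpose(0, 2, 1)
    return EpochArray(data=tensor, fs=fs, channel_names=list(channel_names))


def reject_artifacts(
    epochs: EpochArray,
    amp_uv: float = 100.0,
    slope_uv_per_s: float = 10.0,
    step_uv: float = 25.0,
) -> EpochArray:
    """Mark (epoch, channel) cells violating any of the three criteria:
    |sample| > 100 uV, |linear slope| > 10 uV/s, or successive-sample step
    > 25 uV.  Rejected cells become NaN.
    """
    x = epochs.data
    n_ep, n_ch, spe = x.shape
    amp_bad = np.nanmax(np.abs(x), axis=2) > amp_uv

    t = (np.arange(spe) - (spe - 1) / 2.0) / epochs.fs  # centered seconds
    denom = np.sum(t * t)
    slope = np.tensordot(x, t, axes=([2], [0])) / denom
    slope_bad = np.abs(slope) > slope_uv_per_s

    step_bad = np.nanmax(np.abs(np.diff(x, axis=2)), axis=2) > step_uv

    rejected = epochs.rejected | amp_bad | slope_bad | step_bad
    data = x.copy()
    data[rejected] = np.nan
    return EpochArray(data=data, fs=epochs.fs, channel_names=epochs.channel_names, rejected=rejected)


def eyeblink_regress(epochs: EpochArray, proxy_channel: str = "Fpz") -> EpochArray:
    """Optional blink correction: per-channel least-squares regression of a
    frontal proxy channel, removed from every other channel.

    A lightweight stand-in for template-based ocular correction; disabled by
    default in the pipeline.
    """
    if proxy_channel not in epochs.channel_names:
        raise ValueError(f"proxy channel {proxy_channel!r} missing")
    p = epochs.channel_names.index(proxy_channel)
    flat = epochs.data.transpose(1, 0, 2).reshape(len(epochs.channel_names), -1)
    proxy = flat[p]
    denom = float(proxy @ proxy)
    out = epochs.data.copy()
    if denom > 0:
        gains = flat @ proxy / denom
        gains[p] = 0.0  # keep the proxy channel itself
        out = out - gains[None, :, None] * epochs.data[:, p : p + 1, :]
    return EpochArray(data=out, fs=epochs.fs, channel_names=epochs.channel_names, rejected=epochs.rejected.copy())


def extract_tonic_scl(
    eda: np.ndarray,
    fs: float,
    target_fs: float = 16.0,
    percentile_window_s: float = 10.0,
    smooth_window_s: float = 4.0,
    percentile: float = 50.0,
) -> SclSeries:
    """Tonic skin-conductance level.

    Downsamples to 16 Hz, then estimates the tonic level as a centered
    sliding-window percentile (median over 10 s by default) smoothed by a
    4 s moving average.  This is a deliberately simple tonic/phasic split:
    skin-conductance responses are sparse positive transients, so a running
    median tracks the tonic level underneath them.  The median is preferred
    over a low percentile because, on a smooth trend, a low-percentile
    window behaves like a slope-dependent time shift of up to half the
    window, which badly distorts derivative-based downstream analyses.
    """
    eda = np.asarray(eda, dtype=float).ravel()
    if np.any(eda < 0):
        raise ValueError("negative skin conductance is not physical")
    if fs < target_fs:
        raise ValueError("EDA sampling rate below the 16 Hz target")
    decim = fs / target_fs
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError("sampling rate must be an integer multiple of 16 Hz")
    decim = int(round(decim))
    x = signal.decimate(eda, decim, zero_phase=True) if decim > 1 else eda.copy()

    win_p = max(1, int(round(percentile_window_s * target_fs)))
    tonic = ndimage.percentile_filter(x, percentile=percentile, size=win_p, mode="nearest")
    win_s = max(1, int(round(smooth_window_s * target_fs)))
    tonic = ndimage.uniform_filter1d(tonic, size=win_s, mode="nearest")
    times = np.arange(tonic.size) / target_fs
    return SclSeries(times=times, values=tonic, fs=target_fs)


def baseline_normalize_scl(
    scl: SclSeries, baseline_interval: tuple[float, float], divide: bool = False
) -> SclSeries:
    """Normalize tonic SCL against a baseline interval.

    Subtractive by default (values minus the baseline mean); a divisive
    variant is available since the acquisition literature uses both.
    """
    lo, hi = baseline_interval
    mask = (scl.times >= lo) & (scl.times < hi)
    if not mask.any():
        raise ValueError("baseline interval outside the recording")
    ref = float(np.mean(scl.values[mask]))
    if divide:
        if abs(ref) < 1e-12:
            raise ValueError("zero baseline mean; cannot divide")
        values = scl.values / ref
    else:
        values = scl.values - ref
    return SclSeries(times=scl.times.copy(), values=values, fs=scl.fs)
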