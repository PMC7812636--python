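"""Per-epoch spectral metrics and candidate model enumeration.

Each 1-s epoch gets a Hann-tapered periodogram (1 Hz bins).  Band limits are
anchored to the individual alpha frequency (IAF): theta [IAF-6, IAF-2),
alpha [IAF-2, IAF+2), beta [IAF+2, IAF+16).  ROI band-power series, plus two
global indices -- mental workload (frontal theta / parietal alpha) and
engagement (frontal beta / (frontal alpha + frontal theta)) -- form the
candidate neurometric per model: 2 + 9 ROIs x 3 bands = 29 specifications.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Montage
from .preprocessing import EpochArray

__all__ = [
    "PsdEpochs",
    "BandScheme",
    "ModelSpec",
    "compute_psd",
    "estimate_iaf",
    "define_bands",
    "roi_band_series",
    "workload_series",
    "engagement_series",
    "enumerate_model_specs",
    "WORKLOAD_FRONTAL",
    "WORKLOAD_PARIETAL",
]

#: Channel sets for the two global indices.
WORKLOAD_FRONTAL = ("F3", "F4", "F7", "F8", "Fz")
WORKLOAD_PARIETAL = ("Pz", "P3", "P4", "P7", "P8")

#: Channels over which the individual alpha peak is sought.
IAF_CHANNELS = ("Pz", "P3", "P4", "PO3", "PO4")

BAND_NAMES = ("theta", "alpha", "beta")


@dataclass
class PsdEpochs:
    """Per-epoch, per-channel power spectral density (NaN where rejected)."""

    psd: np.ndarray  # (n_epochs, n_channels, n_bins)
    freqs: np.ndarray  # Hz, uniform spacing
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.psd = np.asarray(self.psd, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.psd.shape[2] != self.freqs.size:
            raise ValueError("frequency axis mismatch")

    @property
    def bin_spacing(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class BandScheme:
    """IAF-anchored frequency bands, half-open [low, high) in Hz."""

    iaf: float
    theta: tuple[float, float]
    alpha: tuple[float, float]
    beta: tuple[float, float]

    def band(self, name: str) -> tuple[float, float]:
        return getattr(self, name)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate 6-node system: SCL and RR fixed, one neurometric.

    ``neurometric`` is ``"Workload"``, ``"Engagement"`` or ``"<ROI>:<band>"``.
    """

    neurometric: str

    @property
    def is_global_index(self) -> bool:
        return self.neurometric in ("Workload", "Engagement")

    @property
    def roi_band(self) -> tuple[str, str] | None:
        if self.is_global_index:
            return None
        roi, band = self.neurometric.split(":")
        return roi, band

    def __str__(self) -> str:  # used as a table key
        return self.neurometric


def compute_psd(epochs: EpochArray) -> PsdEpochs:
    """Hann-tapered periodogram of every (epoch, channel) cell.

    For 1-s epochs the bin spacing is exactly 1 Hz.  Cells marked rejected
    (NaN samples) yield all-NaN PSD rows.
    """
    x = epochs.data
    fs = epochs.fs
    spe = x.shape[2]
    window = sps.get_window("hann", spe)
    scale = 1.0 / (fs * np.sum(window**2))
    rejected = np.isnan(x).any(axis=2)
    filled = np.where(np.isnan(x), x.dtype.type(0), x)
    if x.dtype == np.float32:  # keep single precision through the FFT
        window = window.astype(np.float32)
    spec = np.fft.rfft(filled * window[None, None, :], axis=2)
    psd = (np.abs(spec) ** 2) * scale
    if spe % 2 == 0:
        psd[..., 1:-1] *= 2.0  # one-sided density
    else:
        psd[..., 1:] *= 2.0
    psd[rejected] = np.nan
    freqs = np.fft.rfftfreq(spe, d=1.0 / fs)
    return PsdEpochs(psd=psd, freqs=freqs, channel_names=list(epochs.channel_names))


def estimate_iaf(
    rest_psd: PsdEpochs,
    channels: tuple[str, ...] = IAF_CHANNELS,
    lo: float = 7.0,
    hi: float = 13.0,
    prominence_ratio: float = 1.5,
) -> float:
    """Individual alpha frequency from an eyes-closed baseline.

    Peak of the epoch- and channel-averaged PSD over parietal/parieto-
    occipital channels within 7-13 Hz.  A spectrum with no clear peak
    (flat or monotone) falls back to the canonical 10 Hz with a warning.
    """
    idx = [rest_psd.channel_names.index(c) for c in channels if c in rest_psd.channel_names]
    if not idx:
        raise ValueError("none of the IAF channels are present")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_psd = np.nanmean(rest_psd.psd[:, idx, :], axis=(0, 1))
    band = (rest_psd.freqs >= lo) & (rest_psd.freqs <= hi)
    spectrum = mean_psd[band]
    freqs = rest_psd.freqs[band]
    peaks, _ = sps.find_peaks(spectrum)
    floor = float(np.median(spectrum))
    peaks = [p for p in peaks if spectrum[p] >= prominence_ratio * floor]
    if not peaks:
        warnings.warn("no alpha peak found; falling back to IAF = 10 Hz", stacklevel=2)
        return 10.0
    best = max(peaks, key=lambda p: spectrum[p])
    return float(freqs[best])


def define_bands(iaf: float) -> BandScheme:
    """Klimesch-style IAF-anchored bands within the 1-35 Hz analysis range."""
    if not 7.0 <= iaf <= 13.0:
        raise ValueError("IAF must lie in [7, 13] Hz")
    return BandScheme(
        iaf=float(iaf),
        theta=(iaf - 6.0, iaf - 2.0),
        alpha=(iaf - 2.0, iaf + 2.0),
        beta=(iaf + 2.0, iaf + 16.0),
    )


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return (freqs >= lo) & (freqs < hi)


def _mean_power(psd: PsdEpochs, channels, band: tuple[float, float]) -> np.ndarray:
    """Per-epoch NaN-ignoring mean PSD over given channels and band bins."""
    idx = [psd.channel_names.index(c) for c in channels]
    mask = _band_mask(psd.freqs, band)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    block = psd.psd[:, idx, :][:, :, mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(block, axis=(1, 2))


def roi_band_series(psd: PsdEpochs, montage: Montage, roi: str, band_name: str, bands: BandScheme) -> np.ndarray:
    """Per-epoch mean band power over an ROI's electrodes (NaN where the
    whole cell set is rejected)."""
    if roi not in montage.roi_registry:
        raise ValueError(f"unknown ROI {roi!r}")
    return _mean_power(psd, montage.roi_registry[roi], bands.band(band_name))


def workload_series(psd: PsdEpochs, bands: BandScheme) -> np.ndarray:
    """Mental workload index: frontal theta power / parietal alpha power."""
    num = _mean_power(psd, WORKLOAD_FRONTAL, bands.theta)
    den = _mean_power(psd, WORKLOAD_PARIETAL, bands.alpha)
    out = np.full_like(num, np.nan)
    ok = np.nan_to_num(den, nan=0.0) > 0
    out[ok] = num[ok] / den[ok]
    if (np.nan_to_num(den, nan=1.0) == 0).any():
        warnings.warn("zero parietal alpha power in some epochs; set to NaN", stacklevel=2)
    return out


def engagement_series(psd: PsdEpochs, bands: BandScheme) -> np.ndarray:
    """Engagement index: frontal beta / (frontal alpha + frontal theta)."""
    beta = _mean_power(psd, WORKLOAD_FRONTAL, bands.beta)
    alpha = _mean_power(psd, WORKLOAD_FRONTAL, bands.alpha)
    theta = _mean_power(psd, WORKLOAD_FRONTAL, bands.theta)
    den = alpha + theta
    out = np.full_like(beta, np.nan)
    ok = np.nan_to_num(den, nan=0.0) > 0
    out[ok] = beta[ok] / den[ok]
    if (np.nan_to_num(den, nan=1.0) == 0).any():
        warnings.warn("zero frontal alpha+theta power in some epochs; set to NaN", stacklevel=2)
    return out


def enumerate_model_specs(montage: Montage) -> list[ModelSpec]:
    """All candidate systems: the two global indices plus one spec per
    (ROI, band) pair, in deterministic registry order."""
    specs = [ModelSpec("Workload"), ModelSpec("Engagement")]
    for roi in montage.roi_registry:
        for band in BAND_NAMES:
            specs.append(ModelSpec(f"{roi}:{band}"))
    return specs
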