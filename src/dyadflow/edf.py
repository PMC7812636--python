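"""Minimal reader/writer for the standard EDF format.

Implements the plain (non-plus) European Data Format: a 256-byte fixed
header, one 256-byte header block per signal, and contiguous 1-second data
records of little-endian 16-bit integers.  Only the subset needed to move
multichannel physiological recordings in and out of the pipeline is
supported: a single common sampling rate per file, no annotations, no
discontinuous records.
"""

from __future__ import annotations

import datetime as _dt
import os

import numpy as np

_HDR = 256

__all__ = ["read_edf", "write_edf"]


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def read_edf(path: str | os.PathLike) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file.

    Returns ``(data, fs, channel_names)`` with ``data`` of shape
    (n_samples, n_channels) in the file's physical units.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HDR:
        raise ValueError(f"not an EDF file (too short): {path}")
    n_records = int(_field(raw, 236, 8))
    record_dur = float(_field(raw, 244, 8))
    ns = int(_field(raw, 252, 4))
    hdr_bytes = int(_field(raw, 184, 8))
    if hdr_bytes != _HDR * (ns + 1):
        raise ValueError("inconsistent EDF header size")

    def sig_field(offset: int, width: int) -> list[str]:
        # offset is in bytes from the start of the signal-header block
        base = _HDR + offset
        return [_field(raw, base + i * width, width) for i in range(ns)]

    labels = sig_field(0, 16)
    phys_min = np.array([float(v) for v in sig_field(16 * ns + 80 * ns + 8 * ns, 8)])
    phys_max = np.array([float(v) for v in sig_field(16 * ns + 80 * ns + 8 * ns + 8 * ns, 8)])
    dig_min = np.array([float(v) for v in sig_field(16 * ns + 80 * ns + 8 * ns + 16 * ns, 8)])
    dig_max = np.array([float(v) for v in sig_field(16 * ns + 80 * ns + 8 * ns + 24 * ns, 8)])
    # samples per record field sits after prefiltering (80 bytes per signal)
    spr_base = _HDR + (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80) * ns
    spr = np.array([int(_field(raw, spr_base + i * 8, 8)) for i in range(ns)])
    if len(set(spr.tolist())) != 1:
        raise ValueError("per-channel sampling rates differ; unsupported EDF layout")
    n_per_rec = int(spr[0])
    fs = n_per_rec / record_dur

    payload = np.frombuffer(raw, dtype="<i2", offset=hdr_bytes)
    expected = n_records * ns * n_per_rec
    if payload.size < expected:
        raise ValueError("EDF payload truncated")
    payload = payload[:expected].reshape(n_records, ns, n_per_rec)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - gain * dig_min
    data = payload.transpose(0, 2, 1).reshape(n_records * n_per_rec, ns).astype(float)
    data = data * gain[None, :] + offset[None, :]
    return data, fs, labels


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _num8(v: float) -> str:
    """Format a float into at most 8 ASCII characters without truncation."""
    for prec in range(6, -1, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    raise ValueError(f"value {v} does not fit an 8-char EDF field")


def _num8_outward(v: float, lower: bool) -> str:
    """8-char formatting that never shrinks the physical range.

    Rounding a physical bound toward the data would clip boundary samples,
    so the bound is nudged outward until its 8-char representation still
    covers ``v``.
    """
    s = _num8(v)
    if (float(s) <= v) if lower else (float(s) >= v):
        return s
    eps = max(abs(v), 1e-30) * 1e-7
    for _ in range(12):
        s = _num8(v - eps if lower else v + eps)
        if (float(s) <= v) if lower else (float(s) >= v):
            return s
        eps *= 10.0
    raise ValueError(f"cannot represent bound {v} in an 8-char EDF field")


def write_edf(
    path: str | os.PathLike,
    data: np.ndarray,
    fs: float,
    channel_names: list[str],
    physical_dim: str = "uV",
    patient: str = "X",
) -> None:
    """Write ``data`` (n_samples, n_channels) as a standard EDF file.

    ``fs`` must make one-second records integral. Trailing samples that do
    not fill a whole record are dropped, mirroring acquisition hardware.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (samples, channels)")
    ns = data.shape[1]
    if ns != len(channel_names):
        raise ValueError("channel_names length mismatch")
    n_per_rec = int(round(fs))
    if abs(fs - n_per_rec) > 1e-9:
        raise ValueError("only integer sampling rates are supported")
    n_records = data.shape[0] // n_per_rec
    if n_records < 1:
        raise ValueError("less than one record of data")
    data = data[: n_records * n_per_rec]

    phys_min = np.nanmin(data, axis=0)
    phys_max = np.nanmax(data, axis=0)
    # avoid zero physical range for constant channels
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    # digitize against the values as actually written (8-char precision),
    # rounded outward so no sample falls outside the stored range
    phys_min = np.array([float(_num8_outward(v, lower=True)) for v in phys_min])
    phys_max = np.array([float(_num8_outward(v, lower=False)) for v in phys_max])
    phys_max = np.where(phys_max - phys_min < 1e-12, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[None, :]) / gain[None, :]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    head = b"".join(
        [
            _pad("0", 8),
            _pad(patient, 80),
            _pad("dyadflow", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(_HDR * (ns + 1)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_pad(n, 16) for n in channel_names),
            b"".join(_pad("", 80) for _ in range(ns)),  # transducer
            b"".join(_pad(physical_dim, 8) for _ in range(ns)),
            b"".join(_pad(_num8(v), 8) for v in phys_min),
            b"".join(_pad(_num8(v), 8) for v in phys_max),
            b"".join(_pad(str(dig_min), 8) for _ in range(ns)),
            b"".join(_pad(str(dig_max), 8) for _ in range(ns)),
            b"".join(_pad("", 80) for _ in range(ns)),  # prefiltering
            b"".join(_pad(str(n_per_rec), 8) for _ in range(ns)),
            b"".join(_pad("", 32) for _ in range(ns)),
        ]
    )
    records = digital.reshape(n_records, n_per_rec, ns).transpose(0, 2, 1)
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig)
        fh.write(records.tobytes())
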