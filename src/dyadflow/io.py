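"""Recordings, montages, session manifests and result tables.

A *Recording* is one modality (EEG, ECG or EDA) of one subject on the shared
session clock.  Two on-disk formats are supported: standard EDF, and a
documented CSV dialect (comma-separated, UTF-8, one header row naming the
channels, one column per channel; the sampling rate travels in the session
manifest or is declared by the caller).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import edf

__all__ = [
    "Recording",
    "Montage",
    "SessionManifest",
    "CHANNELS_25",
    "ROI_REGISTRY",
    "default_montage",
    "load_montage",
    "read_recording",
    "write_recording_csv",
    "write_results_table",
    "read_results_table",
    "read_manifest",
    "write_manifest",
]

MODALITIES = ("EEG", "ECG", "EDA")

#: The 25-channel scalp montage used throughout (earlobe-referenced).
CHANNELS_25: tuple[str, ...] = (
    "Fpz", "AFz", "AF3", "AF4", "AF7", "AF8", "Fz", "F3", "F4", "F7", "F8",
    "C5", "C6", "T7", "T8", "CP3", "CP4", "CPz", "Pz", "P3", "P4",
    "PO3", "PO4", "P7", "P8",
)

#: Nine regions of interest, each a named electrode set.
ROI_REGISTRY: dict[str, tuple[str, ...]] = {
    "Frontal": ("F3", "F4", "F7", "F8", "Fz"),
    "rPFC": ("AF4", "AF8", "F8"),
    "lPFC": ("AF3", "AF7", "F7"),
    "PFC": ("AF4", "AF8", "F8", "AF3", "AF7", "F7"),
    "LFT": ("T7", "F7"),
    "Parietal": ("Pz", "P3", "P4", "P7", "P8"),
    "RCP": ("C6", "CP4", "P4"),
    "RTP": ("P8", "T8"),
    "RT": ("C6", "T8"),
}


@dataclass
class Recording:
    """A single-modality multichannel recording on the session clock."""

    subject_id: str
    modality: str
    fs: float
    channel_names: list[str]
    data: np.ndarray  # (n_samples, n_channels); NaN only after artifact marking
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        data = np.asarray(self.data)
        # keep single precision when given; promote everything else to float64
        self.data = data if data.dtype == np.float32 else data.astype(float, copy=False)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel count mismatch between names and data")
        if self.modality == "EEG":
            names, montage = set(self.channel_names), set(CHANNELS_25)
            if not (montage <= names or names <= montage):
                raise ValueError(
                    "EEG channels must be a subset or superset of the 25-channel montage"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channel_names.index(name)]


@dataclass(frozen=True)
class Montage:
    channels: tuple[str, ...]
    roi_registry: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for roi, chans in self.roi_registry.items():
            unknown = set(chans) - set(self.channels)
            if unknown:
                raise ValueError(f"ROI {roi!r} references unknown channels {sorted(unknown)}")
            if not chans:
                raise ValueError(f"ROI {roi!r} is empty")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


def default_montage() -> Montage:
    """The built-in 25-channel montage with its nine-ROI registry."""
    return Montage(channels=CHANNELS_25, roi_registry=dict(ROI_REGISTRY))


def load_montage(spec: Mapping) -> Montage:
    """Build a montage from a mapping with keys ``channels`` and ``rois``."""
    channels = tuple(spec["channels"])
    rois = {str(k): tuple(v) for k, v in spec["rois"].items()}
    return Montage(channels=channels, roi_registry=rois)


@dataclass
class SessionManifest:
    """One dyad/condition session: timing plus per-subject file references."""

    dyad_id: str
    condition: str
    duration: float
    eyes_closed: tuple[float, float]
    rest: tuple[float, float]
    files: dict  # files[subject][modality] -> path (relative to manifest dir)

    CONDITIONS = ("Alone", "CoopNT", "CoopT")

    def __post_init__(self) -> None:
        if self.condition not in self.CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0 < self.duration <= 240:
            raise ValueError("condition duration must be in (0, 240] s")
        for lo, hi in (self.eyes_closed, self.rest):
            if not hi > lo >= 0:
                raise ValueError("baseline intervals must be positive")
        a, b = sorted([self.eyes_closed, self.rest])
        if b[0] < a[1]:
            raise ValueError("baseline intervals overlap")
        if len(self.files) != 2:
            raise ValueError("a session manifest needs exactly two subjects")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.files)


def read_manifest(path: str | os.PathLike) -> SessionManifest:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return SessionManifest(
        dyad_id=str(raw["dyad_id"]),
        condition=raw["condition"],
        duration=float(raw["duration"]),
        eyes_closed=tuple(raw["eyes_closed"]),
        rest=tuple(raw["rest"]),
        files=raw["files"],
    )


def write_manifest(manifest: SessionManifest, path: str | os.PathLike) -> None:
    payload = {
        "dyad_id": manifest.dyad_id,
        "condition": manifest.condition,
        "duration": manifest.duration,
        "eyes_closed": list(manifest.eyes_closed),
        "rest": list(manifest.rest),
        "files": manifest.files,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_recording(
    path: str | os.PathLike,
    modality: str,
    subject_id: str = "",
    fs: float | None = None,
    t0: float = 0.0,
) -> Recording:
    """Read a recording from EDF or from the CSV dialect.

    For CSV the sampling rate must be declared via ``fs`` (it normally comes
    from the session manifest); for EDF it is taken from the file header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        data, file_fs, names = edf.read_edf(path)
        return Recording(subject_id or path.stem, modality, file_fs, list(names), data, t0)
    if suffix in (".csv", ".txt"):
        if fs is None:
            raise ValueError("CSV recordings require a declared sampling rate")
        with open(path) as fh:  # pandas silently renames duplicate headers
            names = [c.strip() for c in fh.readline().rstrip("\n").split(",")]
        if len(set(names)) != len(names):
            raise ValueError("duplicated channel name in CSV header")
        frame = pd.read_csv(path)
        frame.columns = names
        return Recording(subject_id or path.stem, modality, fs, names, frame.to_numpy(float), t0)
    raise ValueError(f"unknown recording format {suffix!r}")


def write_recording_csv(recording: Recording, path: str | os.PathLike) -> None:
    frame = pd.DataFrame(recording.data, columns=recording.channel_names)
    frame.to_csv(path, index=False)


def write_results_table(rows: Sequence[Mapping], path: str | os.PathLike, columns: Sequence[str] | None = None) -> None:
    """Write result rows as CSV with a stable column order.

    All rows must share a schema; an empty row list still writes the header
    when ``columns`` is given (otherwise an empty file with no header would
    be ambiguous, so it raises).
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory {path.parent} does not exist")
    if columns is None:
        if not rows:
            raise ValueError("cannot infer columns from an empty row list")
        columns = list(rows[0].keys())
    for row in rows:
        if set(row.keys()) != set(columns):
            raise ValueError("rows do not share a single schema")
    frame = pd.DataFrame(list(rows), columns=list(columns))
    frame.to_csv(path, index=False)


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
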