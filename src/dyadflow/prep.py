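"""From per-modality series to the aligned 6-column dyad matrix.

Each dyad/condition yields six node series on a common 1 Hz grid, in the
fixed column order (SCLa, RRa, NEUROa, SCLb, RRb, NEUROb): NaN gaps are
spline-interpolated, the tonic SCL is double-differenced to remove its
integrated trend, everything is resampled to integer seconds, z-scored and
checked for stationarity with the augmented Dickey-Fuller test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "NODE_ORDER",
    "DyadMatrix",
    "interpolate_nan_spline",
    "second_difference",
    "resample_to_1hz",
    "zscore",
    "adf_stationarity",
    "assemble_dyad_matrix",
]

NODE_ORDER = ("SCLa", "RRa", "NEUROa", "SCLb", "RRb", "NEUROb")

#: Minimum usable aligned length: a 6-variable VAR of modest order needs a
#: comfortable multiple of its parameter count in observations.
MIN_LENGTH = 60


@dataclass
class DyadMatrix:
    """n x 6 aligned, z-scored 1 Hz node series for one dyad/condition.

    Columns 0-2 belong to subject a, columns 3-5 to subject b.
    """

    values: np.ndarray
    dyad_id: str = ""
    condition: str = ""
    columns: tuple[str, ...] = NODE_ORDER
    prep_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError("dyad matrix must be n x 6")
        if self.values.shape[0] < MIN_LENGTH:
            raise ValueError(f"aligned span shorter than {MIN_LENGTH} s")
        if np.isnan(self.values).any():
            raise ValueError("dyad matrix must be NaN-free")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def block(self, subject: str) -> list[int]:
        """Column indices of one subject ('a' or 'b')."""
        return [0, 1, 2] if subject == "a" else [3, 4, 5]


def interpolate_nan_spline(series: np.ndarray, max_nan_fraction: float = 0.5) -> np.ndarray:
    """Fill NaN samples with a cubic spline through the observed samples.

    Leading/trailing NaN are filled with the nearest observed value (a
    spline extrapolation at the edges is unstable).  Fails when half or
    more of the series is missing.
    """
    x = np.asarray(series, dtype=float).copy()
    bad = np.isnan(x)
    if bad.mean() >= max_nan_fraction:
        raise ValueError(f"{bad.mean():.0%} of samples missing; series unusable")
    if not bad.any():
        return x
    good = np.flatnonzero(~bad)
    if good.size >= 4:
        spline = CubicSpline(good.astype(float), x[good])
        interior = np.flatnonzero(bad & (np.arange(x.size) > good[0]) & (np.arange(x.size) < good[-1]))
        x[interior] = spline(interior.astype(float))
    else:  # degenerate: fall back to linear interpolation
        x[bad] = np.interp(np.flatnonzero(bad), good, x[good])
    # nearest-value edge extension
    first, last = good[0], good[-1]
    x[:first] = x[first]
    x[last + 1 :] = x[last]
    return x


def second_difference(series: np.ndarray) -> np.ndarray:
    """Twice-differenced series (length n-2); removes linear trends and
    integrated-of-order-2 behaviour."""
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to difference twice")
    return np.diff(x, n=2)


def resample_to_1hz(series: np.ndarray, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline evaluation at integer seconds within the sampled span.

    Works for uniform grids and for irregularly-stamped series such as the
    RR tachogram.  Returns (integer_seconds, values).
    """
    times = np.asarray(times, dtype=float)
    x = np.asarray(series, dtype=float)
    if times.shape != x.shape:
        raise ValueError("times/values length mismatch")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    if times[-1] - times[0] < 2.0:
        raise ValueError("span shorter than 2 s")
    t_int = np.arange(np.ceil(times[0]), np.floor(times[-1]) + 1.0)
    spline = CubicSpline(times, x)
    return t_int, spline(t_int)


def zscore(series: np.ndarray) -> np.ndarray:
    """Center and scale to unit (population) standard deviation."""
    x = np.asarray(series, dtype=float)
    sd = float(np.std(x))
    if sd <= 0:
        raise ValueError("constant series cannot be normalized")
    return (x - np.mean(x)) / sd


def adf_stationarity(series: np.ndarray) -> float:
    """Augmented Dickey-Fuller unit-root p-value (lags by AIC).

    Small p rejects the unit root, i.e. supports stationarity.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 20:
        raise ValueError("series too short for the ADF test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(adfuller(x, autolag="AIC")[1])


def assemble_dyad_matrix(
    node_series: dict[str, tuple[np.ndarray, np.ndarray]],
    dyad_id: str = "",
    condition: str = "",
    adf_alpha: float = 0.05,
    run_adf: bool = True,
) -> DyadMatrix:
    """Align six (times, values) node series on their common span.

    ``node_series`` maps each name in ``NODE_ORDER`` to a pair of arrays of
    integer-second time stamps and values.  Columns are trimmed to the
    common span, z-scored, and ADF-checked (a non-stationary column only
    warns; synthetic edge cases must not abort a cohort run).
    """
    missing = set(NODE_ORDER) - set(node_series)
    if missing:
        raise ValueError(f"missing node series: {sorted(missing)}")
    start = max(ts[0] for ts, _ in node_series.values())
    stop = min(ts[-1] for ts, _ in node_series.values())
    n = int(stop - start) + 1
    if n < MIN_LENGTH:
        raise ValueError(f"common span {n} s is below the {MIN_LENGTH} s minimum")

    cols = []
    log: dict = {"start": float(start), "n": n, "adf_p": {}}
    for name in NODE_ORDER:
        ts, vals = node_series[name]
        ts = np.asarray(ts, dtype=float)
        sel = (ts >= start) & (ts <= stop)
        vals = np.asarray(vals, dtype=float)[sel]
        if vals.size != n:
            raise ValueError(f"node {name} is not on the common integer-second grid")
        col = zscore(vals)
        if run_adf:
            p = adf_stationarity(col)
            log["adf_p"][name] = p
            if p >= adf_alpha:
                warnings.warn(
                    f"node {name} fails the ADF stationarity check (p={p:.3f})",
                    stacklevel=2,
                )
        cols.append(col)
    return DyadMatrix(
        values=np.column_stack(cols), dyad_id=dyad_id, condition=condition, prep_log=log
    )
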