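"""Periodogram screening of candidate periodic frequencies.

The periodogram displays the intensity of each frequency present in the
series; frequencies of elevated power are candidates for periodic-component
testing.  The estimate is the raw (untapered, unsmoothed) discrete-Fourier
periodogram of the mean-imputed, demeaned series, on a cycles-per-sample
axis so that hourly data shows the daily cycle at 1/24 ~ 0.0417.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal

from .series import PeriodicSeries

__all__ = ["Periodogram", "Peak", "periodogram", "peak_candidates", "write_periodogram"]


@dataclass
class Periodogram:
    """One-sided periodogram on a strictly increasing frequency grid."""

    freqs: np.ndarray  # cycles per sample, in (0, 0.5]
    power: np.ndarray  # nonnegative intensity, 'spectrum' scaling

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have matching shapes")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    def total_power(self) -> float:
        return float(self.power.sum())


@dataclass(frozen=True)
class Peak:
    frequency: float
    power: float

    @property
    def period(self) -> float:
        """Implied period 1/f in samples."""
        return 1.0 / self.frequency


def periodogram(x: Union[PeriodicSeries, np.ndarray]) -> Periodogram:
    """Raw periodogram of the series, missing values filled with the mean.

    Mean imputation adds no power at nonzero frequencies in expectation and
    is adequate for peak screening; the zero-frequency term is dropped.
    """
    v = x.values if isinstance(x, PeriodicSeries) else np.asarray(x, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("periodogram requires at least 4 non-missing values")
    filled = np.where(finite, v, np.nanmean(v))
    freqs, power = signal.periodogram(
        filled, fs=1.0, window="boxcar", detrend="constant", scaling="spectrum"
    )
    return Periodogram(freqs=freqs[1:], power=power[1:])


def peak_candidates(
    p: Periodogram, top_n: int, min_freq: float = 0.0
) -> List[Peak]:
    """Top ``top_n`` local maxima of the periodogram, ranked by power.

    Ties in power are broken in favour of the lower frequency.  ``min_freq``
    restricts the screen to frequencies at or above it — useful for reading
    the high-frequency region past the trend/low-frequency rise, as one does
    visually on the plotted periodogram.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    pw = p.power
    # strict local maxima; the grid ends count if they dominate their one neighbour
    left = np.r_[-np.inf, pw[:-1]]
    right = np.r_[pw[1:], -np.inf]
    is_peak = (pw > left) & (pw > right) & (p.freqs >= min_freq)
    idx = np.flatnonzero(is_peak)
    order = idx[np.lexsort((p.freqs[idx], -pw[idx]))]
    return [Peak(float(p.freqs[i]), float(pw[i])) for i in order[:top_n]]


def write_periodogram(p: Periodogram, path) -> None:
    """Two-column CSV (frequency, power) for external plotting."""
    pd.DataFrame({"frequency": p.freqs, "power": p.power}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_periodogram(path) -> Periodogram:
    df = pd.read_csv(path)
    return Periodogram(df["frequency"].to_numpy(float), df["power"].to_numpy(float))
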