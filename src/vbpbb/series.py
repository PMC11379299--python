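"""Regularly sampled time series container.

The analysis operates on a fixed hourly grid: values are stored as a float
array in which missing observations are ``NaN``; an optional start timestamp
anchors the grid to wall-clock time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class CleaningReport:
    """Counts accumulated while reading raw files onto the hourly grid."""

    retained: int = 0
    coded_errors: int = 0
    missing_hours: int = 0
    rejected_timestamps: int = 0

    def as_dict(self) -> dict:
        return {
            "retained": self.retained,
            "coded_errors": self.coded_errors,
            "missing_hours": self.missing_hours,
            "rejected_timestamps": self.rejected_timestamps,
        }


@dataclass
class PeriodicSeries:
    """A regularly sampled series; ``NaN`` marks missing observations.

    Parameters
    ----------
    values
        Float array of observations on a regular grid.
    start
        Timestamp of the first sample, or ``None`` for an abstract grid.
    step
        Sampling interval (default one hour, the native resolution of the
        pollutant data this package targets).
    cleaning
        Optional :class:`CleaningReport` attached by the file reader.
    """

    values: np.ndarray
    start: Optional[pd.Timestamp] = None
    step: pd.Timedelta = field(default_factory=lambda: pd.Timedelta(hours=1))
    cleaning: Optional[CleaningReport] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.start is not None:
            self.start = pd.Timestamp(self.start)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        if self.start is None:
            raise ValueError("series has no start timestamp")
        return pd.date_range(self.start, periods=self.n, freq=self.step)

    def grand_mean(self) -> float:
        if self.n_valid == 0:
            raise ValueError("series has no valid observations")
        return float(np.nanmean(self.values))

    def to_frame(self) -> pd.DataFrame:
        idx = self.timestamps if self.start is not None else pd.RangeIndex(self.n)
        return pd.DataFrame({"value": self.values}, index=idx)

    @classmethod
    def from_values(cls, values, start=None) -> "PeriodicSeries":
        return cls(values=np.asarray(values, dtype=float), start=start)


def write_tidy(series: PeriodicSeries, path) -> None:
    """Write a two-column CSV (ISO-8601 hour, value); missing values blank."""
    df = series.to_frame()
    df.index.name = "timestamp"
    df.to_csv(path, float_format="%.6f", na_rep="")


def read_tidy(path) -> PeriodicSeries:
    df = pd.read_csv(path, index_col=0, parse_dates=True)
    idx = pd.DatetimeIndex(df.index)
    if len(idx) > 1:
        step = idx[1] - idx[0]
        if not (np.diff(idx.asi8) == step.value).all():
            raise ValueError("timestamps do not form a regular grid")
    else:
        step = pd.Timedelta(hours=1)
    return PeriodicSeries(df.iloc[:, 0].to_numpy(float), start=idx[0], step=step)
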