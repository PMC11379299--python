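"""Reader for EPA AQS pre-generated hourly data files.

The AQS pre-generated hourly files (``hourly_42602_YYYY.csv`` for NO2) hold
one row per instrument reading with site coordinates, local and GMT
timestamps, the sample measurement and a qualifier column.  This module
selects one monitoring site by coordinates, strips coded-error readings,
averages replicate readings within each hour and places the result on a
continuous hourly grid with absent hours marked missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .series import CleaningReport, PeriodicSeries

__all__ = ["SiteSelector", "read_hourly", "cleaning_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteSelector:
    """Monitoring-site filter by printed coordinates.

    Coordinates are matched with a decimal tolerance (default 1e-5 degrees,
    the precision the files print).
    """

    longitude: float
    latitude: float
    parameter: str = "42602"  # NO2
    datum: str = "WGS84"
    tolerance: float = 1e-5

    def __post_init__(self) -> None:
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude out of range: {self.longitude}")
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude out of range: {self.latitude}")


def _match_site(df: pd.DataFrame, sel: SiteSelector) -> pd.Series:
    lat = pd.to_numeric(df["Latitude"], errors="coerce")
    lon = pd.to_numeric(df["Longitude"], errors="coerce")
    ok = (np.abs(lat - sel.latitude) <= sel.tolerance) & (
        np.abs(lon - sel.longitude) <= sel.tolerance
    )
    if sel.parameter:
        code = df["Parameter Code"].astype(str).str.strip()
        name = df.get("Parameter Name", pd.Series("", index=df.index)).astype(str)
        ok &= (code == str(sel.parameter)) | (name == str(sel.parameter))
    if sel.datum and "Datum" in df:
        ok &= df["Datum"].astype(str).str.strip() == sel.datum
    return ok


def read_hourly(
    paths: Union[str, Path, Sequence[Union[str, Path]]],
    selector: SiteSelector,
    start: Optional[str] = None,
    end: Optional[str] = None,
    time_basis: str = "local",
    error_values: Sequence[float] = (-999.0,),
) -> PeriodicSeries:
    """Read AQS hourly file(s) for one site onto a continuous hourly grid.

    Multiple readings within an hour (e.g. collocated monitors, several
    POCs) are averaged; rows with a non-empty qualifier or a sentinel
    measurement are excluded and counted as coded errors; hours with no
    reading are NaN.  ``start``/``end`` bound the grid (inclusive); by
    default the grid spans the data's own range.

    ``time_basis`` selects the local-standard-time columns (default — the
    daily and weekly periodicities of human activity are phase-locked to
    local time) or ``"gmt"``.
    """
    if time_basis not in ("local", "gmt"):
        raise ValueError(f"time_basis must be 'local' or 'gmt', got {time_basis!r}")
    if isinstance(paths, (str, Path)):
        paths = [paths]

    date_col = "Date Local" if time_basis == "local" else "Date GMT"
    time_col = "Time Local" if time_basis == "local" else "Time GMT"

    frames = []
    for p in paths:
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
        frames.append(df[_match_site(df, selector)])
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if df.empty:
        raise ValueError(
            f"no rows match site (lon={selector.longitude}, lat={selector.latitude}, "
            f"parameter={selector.parameter})"
        )

    report = CleaningReport()

    ts = pd.to_datetime(
        df[date_col].str.strip() + " " + df[time_col].str.strip(), errors="coerce"
    )
    bad_ts = ts.isna()
    report.rejected_timestamps = int(bad_ts.sum())
    if report.rejected_timestamps:
        log.warning("rejected %d rows with unparseable timestamps",
                    report.rejected_timestamps)
    df = df[~bad_ts]
    ts = ts[~bad_ts]

    value = pd.to_numeric(df["Sample Measurement"], errors="coerce")
    qualifier = df.get("Qualifier", pd.Series("", index=df.index)).astype(str).str.strip()
    is_error = (qualifier != "") | value.isna()
    for sentinel in error_values:
        is_error |= np.isclose(value.fillna(np.inf), sentinel)
    report.coded_errors = int(is_error.sum())

    ts = ts[~is_error]
    value = value[~is_error]
    report.retained = int(len(value))

    hours = ts.dt.floor("h")
    by_hour = value.groupby(hours.values).mean()

    lo = pd.Timestamp(start) if start else (by_hour.index.min() if len(by_hour) else None)
    hi = pd.Timestamp(end) if end else (by_hour.index.max() if len(by_hour) else None)
    if lo is None or hi is None or hi < lo:
        warnings.warn("empty selection after cleaning; returning empty series",
                      stacklevel=2)
        series = PeriodicSeries(np.array([], dtype=float), start=lo)
        series.cleaning = report
        return series

    grid = pd.date_range(lo.floor("h"), hi.floor("h"), freq="h")
    on_grid = by_hour.reindex(grid)
    report.missing_hours = int(on_grid.isna().sum())

    series = PeriodicSeries(on_grid.to_numpy(float), start=grid[0])
    series.cleaning = report
    return series


def cleaning_report(series: PeriodicSeries) -> CleaningReport:
    """Cleaning totals attached by :func:`read_hourly`."""
    if series.cleaning is None:
        raise ValueError("series carries no cleaning report (not read by read_hourly)")
    return series.cleaning
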