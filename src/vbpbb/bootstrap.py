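"""Periodic-mean estimation and seasonal block bootstrap confidence bands.

Two resampling routes are provided for a periodically correlated series:

* **GSBB** — the General Seasonal Block Bootstrap resamples the raw series
  in blocks whose start positions share the phase (mod period) of the slot
  they fill, preserving the periodic structure at that period.
* **VBPBB** — the Variable Bandpass Periodic Block Bootstrap first isolates
  the periodic component at the frequency of interest with the KZFT
  bandpass filter (:mod:`vbpbb.kzft`) and applies the same phase-preserving
  block resampling to the filtered component, so interfering frequencies,
  trend and broadband noise are excluded before resampling.

A confidence band assembles a per-phase percentile interval at every phase
of the period.  The default band pools the resampled *values* at each phase
(as deviations from each replicate's grand mean) and takes their
``alpha/2`` and ``1 - alpha/2`` quantiles; ``band_type="mean"`` instead
uses the bootstrap distribution of the per-phase *mean*.  The pooled-value
band is the construction under which the horizontal-line significance rule
is calibrated (see docs/methods.md); the mean band is sharply
anti-conservative under that rule when the period has many phases.

Significance follows the horizontal-line criterion: the band shows periodic
mean variation different from zero exactly when no horizontal line fits
inside it, i.e. when the largest lower limit exceeds the smallest upper
limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .kzft import ComponentEstimate, FilterSpec, bandpass
from .series import PeriodicSeries

__all__ = [
    "BootstrapConfig",
    "ConfidenceBand",
    "BandSummary",
    "SignificanceResult",
    "WidthRatio",
    "periodic_mean",
    "gsbb_resample",
    "band_from_bootstrap",
    "significance",
    "band_extremes",
    "width_ratio",
    "r_squared",
    "summarize",
    "write_band",
    "read_band",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings shared by both bootstrap routes.

    ``block_length`` defaults to the period itself (one full cycle per
    block); ``circular`` wraps blocks past the series end, with the
    analysed region trimmed to whole periods so wrapped blocks stay in
    phase.  Replicate ``r`` draws from a stream seeded by ``(seed, r)`` so
    the replicate set is order-independent.
    """

    n_boot: int = 1000
    block_length: Optional[int] = None
    alpha: float = 0.05
    seed: int = 0
    circular: bool = True
    band_type: str = "value"  # "value" (pooled resampled values) or "mean"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        if self.band_type not in ("value", "mean"):
            raise ValueError(f"unknown band_type {self.band_type!r}")
        if self.block_length is not None and self.block_length < 1:
            raise ValueError("block_length must be positive")


@dataclass
class ConfidenceBand:
    """Per-phase lower/center/upper periodic-mean deviations for one period.

    All three arrays have length ``period`` and are deviations from the
    grand mean of the analysed series (the zero line of the band plots).
    """

    period: int
    lower: np.ndarray
    center: np.ndarray
    upper: np.ndarray
    method: str  # "GSBB" or "VBPBB"
    alpha: float = 0.05
    source_spec: Optional[FilterSpec] = None
    band_type: str = "value"
    n_boot: int = 0

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        for name in ("lower", "center", "upper"):
            arr = getattr(self, name)
            if arr.shape != (self.period,):
                raise ValueError(f"{name} must have length period={self.period}")
        if np.any(self.lower > self.center + 1e-12) or np.any(
            self.center > self.upper + 1e-12
        ):
            raise ValueError("band must satisfy lower <= center <= upper")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


class SignificanceResult(NamedTuple):
    significant: bool
    pct_excluding_zero: float


class WidthRatio(NamedTuple):
    median: float
    q25: float
    q75: float


@dataclass
class BandSummary:
    """Band extremes and comparison statistics (one table row per band)."""

    min_range: Tuple[float, float]
    max_range: Tuple[float, float]
    pct_excluding_zero: float
    significant: bool
    median_width_ratio: Optional[float] = None


def _values_of(x: Union[PeriodicSeries, ComponentEstimate, np.ndarray]) -> np.ndarray:
    if isinstance(x, PeriodicSeries):
        return x.values
    if isinstance(x, ComponentEstimate):
        return x.masked_values()
    return np.asarray(x, dtype=float)


def periodic_mean(
    x: Union[PeriodicSeries, ComponentEstimate, np.ndarray],
    period: int,
    phase_offset: int = 0,
) -> np.ndarray:
    """Per-phase means as deviations from the grand mean of valid values.

    Phase ``s`` collects the valid observations at indices ``i`` with
    ``(phase_offset + i) % period == s``.  A phase with no valid
    observation raises, naming the phase.
    """
    v = _values_of(x)
    d = int(period)
    if d < 2:
        raise ValueError(f"period must be >= 2, got {period}")
    n = v.size
    phases = (phase_offset + np.arange(n)) % d
    valid = np.isfinite(v)
    counts = np.bincount(phases[valid], minlength=d)
    if np.any(counts == 0):
        empty = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"phase {empty} has no valid observations")
    sums = np.bincount(phases[valid], weights=v[valid], minlength=d)
    grand = v[valid].mean()
    return sums / counts - grand


def _resample_indices(
    rng: np.random.Generator, n: int, period: int, block_length: int, circular: bool
) -> np.ndarray:
    """Index vector of one GSBB pseudo-series of length ``n``.

    Slot ``t`` (t = 0, b, 2b, ...) is filled by a block starting at a
    position drawn uniformly among those sharing ``t``'s phase mod period.
    """
    b = int(block_length)
    d = int(period)
    slots = np.arange(0, n, b)
    rem = slots % d
    if circular:
        counts = (n - rem + d - 1) // d
    else:
        hi = n - b
        if hi < 0:
            raise ValueError("block_length exceeds series length")
        counts = np.where(rem <= hi, (hi - rem) // d + 1, 0)
        if np.any(counts == 0):
            raise ValueError(
                "no admissible non-circular block start for some phase; "
                "use circular=True or a shorter block"
            )
    starts = rem + d * rng.integers(0, counts)
    idx = starts[:, None] + np.arange(b)[None, :]
    if circular:
        idx %= n
    return idx.reshape(-1)[:n]


def _replicate_rng(seed: int, r: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(r))))


def gsbb_resample(
    x: Union[PeriodicSeries, np.ndarray],
    period: int,
    cfg: BootstrapConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """One GSBB bootstrap pseudo-series of the original length.

    With ``period = 1`` every position shares the same phase and this
    reduces to the ordinary (non-seasonal) moving block bootstrap.
    """
    v = _values_of(x)
    n = v.size
    d = int(period)
    if d < 1:
        raise ValueError("period must be >= 1")
    if d > n:
        raise ValueError(f"period {d} exceeds series length {n}")
    b = cfg.block_length if cfg.block_length is not None else d
    if rng is None:
        rng = _replicate_rng(cfg.seed, 0)
    return v[_resample_indices(rng, n, d, min(b, n), cfg.circular)]


def _prepare_analysis_region(
    x: Union[PeriodicSeries, np.ndarray],
    period: int,
    cfg: BootstrapConfig,
    method: str,
    spec: Optional[FilterSpec],
    edges: str,
    max_missing_frac: float,
) -> Tuple[np.ndarray, int]:
    """Series (or filtered component) restricted to the resampled region.

    Returns the local value array and the global phase offset of its first
    sample.  For VBPBB the raw series is bandpass-filtered and only the
    component's valid (edge-complete) region is resampled; the band's phase
    grid still refers to global phases.
    """
    if method == "VBPBB":
        if spec is None:
            raise ValueError("VBPBB requires a FilterSpec")
        comp = bandpass(x, spec, edges=edges, max_missing_frac=max_missing_frac)
        y = comp.masked_values()
        idx = np.flatnonzero(comp.valid_mask)
        if idx.size == 0:
            raise ValueError("no valid samples remain after bandpass filtering")
        y = y[idx[0] : idx[-1] + 1]
        offset = int(idx[0])
    elif method == "GSBB":
        y = _values_of(x).copy()
        offset = 0
    else:
        raise ValueError(f"unknown method {method!r}")

    d = int(period)
    if cfg.circular:
        n_use = (y.size // d) * d
        y = y[:n_use]
    if y.size < 2 * d:
        raise ValueError(
            f"insufficient data: {y.size} usable samples for period {d} "
            "(need at least two full cycles)"
        )
    return y, offset


def band_from_bootstrap(
    x: Union[PeriodicSeries, np.ndarray],
    period: int,
    cfg: BootstrapConfig,
    method: str = "GSBB",
    spec: Optional[FilterSpec] = None,
    edges: str = "truncate",
    max_missing_frac: float = 0.2,
) -> ConfidenceBand:
    """Bootstrap confidence band for the periodic mean at ``period``.

    The center is the point estimate from the unresampled input; lower and
    upper are per-phase percentile limits over ``cfg.n_boot`` replicates
    (pooled resampled values by default, replicate means with
    ``band_type="mean"``), with linear-interpolation quantiles.
    """
    if cfg.n_boot < 100:
        raise ValueError("n_boot must be >= 100 for band construction")
    d = int(period)
    if d < 2:
        raise ValueError("period must be >= 2")
    y, offset = _prepare_analysis_region(
        x, d, cfg, method, spec, edges, max_missing_frac
    )
    n = y.size
    b = cfg.block_length if cfg.block_length is not None else d
    b = min(int(b), n)

    center = periodic_mean(y, d, phase_offset=offset)

    phases = (offset + np.arange(n)) % d
    order = np.argsort(phases, kind="stable")
    counts = np.bincount(phases, minlength=d)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))

    B = cfg.n_boot
    qs = (cfg.alpha / 2.0, 1.0 - cfg.alpha / 2.0)
    chunk = max(1, int(4_000_000 // max(n, 1)))

    if cfg.band_type == "mean":
        devs = np.empty((B, d))
    else:
        pooled_chunks = []

    for c0 in range(0, B, chunk):
        rows = range(c0, min(c0 + chunk, B))
        idx = np.empty((len(rows), n), dtype=np.int64)
        for j, r in enumerate(rows):
            idx[j] = _resample_indices(_replicate_rng(cfg.seed, r), n, d, b, cfg.circular)
        Y = y[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            g = np.nanmean(Y, axis=1)
        D = (Y - g[:, None])[:, order]
        if cfg.band_type == "mean":
            mask = np.isfinite(D)
            s = np.add.reduceat(np.where(mask, D, 0.0), starts, axis=1)
            c = np.add.reduceat(mask.astype(float), starts, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                devs[c0 : c0 + len(rows)] = np.where(c > 0, s / np.maximum(c, 1), np.nan)
        else:
            pooled_chunks.append(D)

    if cfg.band_type == "mean":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lower, upper = np.nanquantile(devs, qs, axis=0, method="linear")
    else:
        D_all = np.vstack(pooled_chunks)
        lower = np.empty(d)
        upper = np.empty(d)
        bounds = np.append(starts, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for s_ in range(d):
                seg = D_all[:, bounds[s_] : bounds[s_ + 1]]
                lo, hi = np.nanquantile(seg, qs, method="linear")
                lower[s_], upper[s_] = lo, hi

    # percentile limits of a finite pool can fail to bracket the point
    # estimate by a hair for tiny/degenerate pools; the band is defined to
    # contain its center
    lower = np.minimum(lower, center)
    upper = np.maximum(upper, center)
    return ConfidenceBand(
        period=d,
        lower=lower,
        center=center,
        upper=upper,
        method=method,
        alpha=cfg.alpha,
        source_spec=spec,
        band_type=cfg.band_type,
        n_boot=B,
    )


def significance(band: ConfidenceBand) -> SignificanceResult:
    """Horizontal-line criterion plus the per-phase zero-exclusion tally.

    The band indicates periodic mean variation significantly different from
    zero when no horizontal line fits inside it: the maximum over phases of
    the lower limit exceeds the minimum over phases of the upper limit.
    """
    sig = bool(band.lower.max() > band.upper.min())
    excl = (band.lower > 0.0) | (band.upper < 0.0)
    return SignificanceResult(sig, float(100.0 * excl.mean()))


def band_extremes(
    band: ConfidenceBand,
) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """CI at the band's lowest and highest center phases (ties: earliest)."""
    i_min = int(np.argmin(band.center))
    i_max = int(np.argmax(band.center))
    return (
        (float(band.lower[i_min]), float(band.upper[i_min])),
        (float(band.lower[i_max]), float(band.upper[i_max])),
    )


def width_ratio(gsbb: ConfidenceBand, vbpbb: ConfidenceBand) -> WidthRatio:
    """Median and quartiles of the per-phase GSBB/VBPBB band-width ratio."""
    if gsbb.period != vbpbb.period:
        raise ValueError("bands must share the same period and phase grid")
    wv = vbpbb.width
    if np.any(wv <= 0):
        raise ValueError("degenerate zero-width VBPBB interval")
    ratios = gsbb.width / wv
    q25, med, q75 = np.quantile(ratios, [0.25, 0.5, 0.75])
    return WidthRatio(float(med), float(q25), float(q75))


def r_squared(
    component: ComponentEstimate, x: Union[PeriodicSeries, np.ndarray]
) -> float:
    """Proportion of series variation explained by one periodic component.

    Squared Pearson correlation between the component and the original
    series over their joint valid region.
    """
    v = _values_of(x)
    joint = component.valid_mask & np.isfinite(v)
    if not joint.any():
        raise ValueError("component and series share no valid samples")
    a = component.values[joint]
    b = v[joint]
    if np.ptp(a) == 0.0 or a.std() == 0.0:
        warnings.warn("constant component; R^2 defined as 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def summarize(
    band: ConfidenceBand, ratio: Optional[WidthRatio] = None
) -> BandSummary:
    """Table-row summary: extremes, zero-exclusion tally, significance."""
    min_range, max_range = band_extremes(band)
    sig = significance(band)
    return BandSummary(
        min_range=min_range,
        max_range=max_range,
        pct_excluding_zero=sig.pct_excluding_zero,
        significant=sig.significant,
        median_width_ratio=None if ratio is None else ratio.median,
    )


def write_band(band: ConfidenceBand, path) -> None:
    """CSV with columns phase, lower, center, upper, method, period."""
    pd.DataFrame(
        {
            "phase": np.arange(band.period),
            "lower": band.lower,
            "center": band.center,
            "upper": band.upper,
            "method": band.method,
            "period": band.period,
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_band(path, alpha: float = 0.05) -> ConfidenceBand:
    df = pd.read_csv(path)
    period = int(df["period"].iloc[0])
    return ConfidenceBand(
        period=period,
        lower=df["lower"].to_numpy(float),
        center=df["center"].to_numpy(float),
        upper=df["upper"].to_numpy(float),
        method=str(df["method"].iloc[0]),
        alpha=alpha,
    )
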