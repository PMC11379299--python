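# vbpbb — Variable Bandpass Periodic Block Bootstrap

Confidence bands for the periodic mean of long, noisy, periodically
correlated time series — built for hourly air-pollutant records (NO₂ and
similar), usable for any regularly sampled series with daily / weekly /
annual structure.

## The problem

An hourly pollutant series mixes several periodic components (a dominant
annual cycle, weaker daily and weekly cycles and their harmonics), a slow
trend, and heavy observational noise. The classical *General Seasonal Block
Bootstrap* (GSBB) resamples the raw series in blocks whose start positions
share the phase (mod period) of the slot they fill, which preserves the
periodic structure at one period — but every other component, the trend and
the noise ride along into each resample, inflating the confidence band and
hiding real periodic variation.

The *Variable Bandpass Periodic Block Bootstrap* (VBPBB) first isolates the
periodic component of interest with a **Kolmogorov–Zurbenko Fourier
Transform** (KZFT) bandpass filter and then applies the same
phase-preserving block bootstrap to the filtered component alone. The KZFT
with window `m` (odd), iterations `k` and centre frequency `ν` is

    KZFT_{m,k,ν}(X)(t) = Σ_{u=-k(m-1)/2}^{k(m-1)/2}  (a_u^{m,k} / m^k) · e^{-i2πν(t+u)} · X(t+u)

where the weights `a_u^{m,k}` are the coefficients of
`(1 + z + … + z^{m-1})^k` — the k-fold self-convolution of a uniform
moving average. The real bandpass component is recovered as
`2·Re(e^{+i2πνt}·z(t))`. The window follows the `m = 2p + 1` rule for a
target period `p`, placing the filter's first null halfway to the
neighbouring frequencies; `k = 2` by default.

For each period the package builds a per-phase 95% percentile band of
periodic-mean deviations from the grand mean, and applies the
**horizontal-line criterion**: the periodic variation is significant when
no horizontal line fits inside the band (the largest lower limit exceeds
the smallest upper limit).

## Worked example

A synthetic hourly series at desk scale — 20,000 samples around a 20.57 ppb
mean with a 6 ppb "annual" cycle (period shortened to 720 samples so ~28
cycles fit), weak daily/weekly cycles, an 8 ppb noise floor, 2% missing
hours:

```python
import numpy as np
from vbpbb import (BootstrapConfig, Component, FilterSpec, HarmonicTerm,
                   SyntheticSpec, band_from_bootstrap, generate,
                   significance, width_ratio)

spec = SyntheticSpec(
    n=20_000, grand_mean=20.57, trend_slope=-3e-5,
    components=(Component(period=720.0, amplitude=6.0),
                Component(period=24.0, amplitude=0.9,
                          harmonics=(HarmonicTerm(multiple=2, amplitude=0.6),)),
                Component(period=168.0, amplitude=0.4)),
    noise_sd=8.0, missing_rate=0.02, n_coded_errors=5, seed=11,
)
series, truth = generate(spec)

cfg = BootstrapConfig(n_boot=1000, seed=0)
fspec = FilterSpec.from_period(720, k=2)          # m = 1441
vband = band_from_bootstrap(series, 720, cfg, method="VBPBB", spec=fspec)
gband = band_from_bootstrap(series, 720, cfg, method="GSBB")

sv, sg = significance(vband), significance(gband)
ratio = width_ratio(gband, vband)
print(f"VBPBB significant: {sv.significant} "
      f"({sv.pct_excluding_zero:.1f}% of phases exclude zero)")
print(f"GSBB  significant: {sg.significant} "
      f"({sg.pct_excluding_zero:.1f}% of phases exclude zero)")
print(f"median GSBB/VBPBB width ratio: {ratio.median:.2f} "
      f"(quartiles {ratio.q25:.2f}-{ratio.q75:.2f})")
```

prints

```
VBPBB significant: True (94.4% of phases exclude zero)
GSBB  significant: True (0.3% of phases exclude zero)
median GSBB/VBPBB width ratio: 38.20 (quartiles 29.45-52.21)
```

Both routes detect the injected annual-scale cycle, but the VBPBB band is
an order of magnitude narrower and excludes zero at almost every phase,
while the raw-series GSBB band barely does anywhere — filtering out the
other components and the noise floor before resampling is what sharpens
the estimate.

## Command line

```sh
vbpbb simulate --n 20000 --seed 3 --out series.csv
vbpbb analyze --input series.csv --frequencies "daily=1/24,weekly=1/168" \
      --n-boot 1000 --seed 1 --outdir reports/
vbpbb compare --gsbb reports/band_daily_gsbb.csv --vbpbb reports/band_daily_vbpbb.csv
```

`analyze` accepts EPA AQS pre-generated hourly files directly
(`--aqs --longitude -118.22688 --latitude 34.06659`), screens the
periodogram, and writes per-frequency band CSVs plus a summary table
(band extremes, width ratios, significance, R² per component) and a JSON
run log. The default frequency registry tests eight frequencies: annual
(1/8760), its second harmonic, the 1/400 "biweekly" screen, weekly
(1/168), its harmonic, and daily (1/24) with two harmonics.

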