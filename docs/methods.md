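# Methods

## Model and estimand

The package treats an hourly series `X(t)` as periodically correlated: its
mean structure repeats with one or more fixed periods (daily, weekly,
annual, plus harmonics), superposed on a slow trend and broadband noise.
For a period `p` the estimand is the *periodic mean*: the vector of
per-phase means over observations at indices congruent mod `p`, reported
as deviations from the grand mean of the analysed series. All inference is
about whether and how this vector departs from zero.

## KZFT bandpass filter

The Kolmogorov–Zurbenko Fourier Transform is an iterated moving average
modulated by a complex exponential. With window `m` (odd) and `k`
iterations, the kernel weights are the normalized coefficients of
`(1 + z + … + z^{m-1})^k`, computed here by k-fold self-convolution of the
uniform kernel — exact to machine precision at the sizes used, and verified
in the tests against an independent symbolic polynomial expansion.

Two implementation conventions matter:

* **Demodulated output.** `kzft_transform` returns
  `z(t) = Σ_u w_u e^{-i2πν(t+u)} X(t+u)`, i.e. the complex amplitude
  demodulated in `t` (the convention of the R `kza` package), so the real
  component is `2·Re(e^{+i2πνt} z(t))`. An undemodulated variant differs
  only by the unit phase factor `e^{-i2πνt}`; the modulus is identical.
  The demodulated form is the one under which the reconstruction formula
  recovers a unit cosine exactly, which the test suite asserts.
* **Window rule.** `window_for_period` implements `m = 2p + 1`, the
  smallest odd window whose first transfer-function null falls within one
  neighbouring-frequency spacing; `k = 2` is the default iteration count.
  Both are plain parameters — there is no automatic optimisation of `m`
  or `k`, which remains an open problem for this family of methods.

**Edges.** The kernel spans `k(m-1)/2` samples on each side. By default
(`edges="truncate"`) the first and last `k(m-1)/2` output samples are
flagged invalid and excluded from all downstream statistics.
`edges="renormalize"` instead renormalizes the kernel over the in-range
samples and keeps the edge region, at the price of extra variance there.
Both modes are provided because the choice is genuinely open; truncation
is the conservative default.

**Missing values.** Interior gaps are handled by renormalizing the kernel
weights over the observed in-window samples, provided the missing weight
fraction is at most `max_missing_frac` (default 0.2); beyond that the
output sample is flagged invalid. Rationale: isolated missing hours should
not void a half-window of otherwise clean filter output, but a window that
is mostly gap carries no information about the component.

## Bootstrap bands

**GSBB.** One pseudo-series is assembled from blocks of length `b`
(default: the period `d`, one full cycle per block) whose start positions
are drawn uniformly among positions with the same phase (mod `d`) as the
slot they fill. `circular=True` (default) wraps blocks past the series
end; because a wrapped block only stays in phase when the series length is
a multiple of the period, the analysed region is trimmed to whole periods
in circular mode. With `period=1` the scheme reduces to the ordinary
moving block bootstrap.

**VBPBB.** The series is bandpass-filtered at `ν = 1/d` first; resampling
runs on the filtered component's valid (edge-complete) region, with phases
kept on the global grid. Everything else is identical to GSBB — the two
routes differ only in what is resampled.

**Band construction.** For each phase the band is the
`(α/2, 1−α/2)` percentile interval (linear-interpolation quantiles) of the
pooled resampled *values* at that phase, each taken as a deviation from
its replicate's grand mean; the center is the point estimate from the
unresampled input, and the limits are widened to bracket it in the rare
degenerate-pool case. An alternative `band_type="mean"` uses the bootstrap
distribution of the per-phase *mean* instead.

The pooled-value band is the default for two reasons. First, it is the
construction under which the horizontal-line significance rule is
calibrated: with per-phase mean-CIs, the maximum of hundreds of
near-independent phase means exceeds the pointwise interval width with
probability approaching one even under the null, so the rule would fire on
pure noise almost always (the simulation in `tests/test_acceptance.py`
measures a 0% firing rate for the default band and a majority firing rate
for the mean band on white noise). Second, its width reflects the
phase-conditional spread of the (filtered) data, which is the scale on
which this method family's band comparisons are reported — under GSBB it is
nearly period-independent (the raw data distribution), while under VBPBB it
shrinks with the filter bandwidth, which is precisely the contrast the
method is designed to expose.

**Significance.** A band is significant when no horizontal line fits
inside it: `max_s lower(s) > min_s upper(s)`. The per-phase tally of
intervals excluding zero is reported alongside. No multiple-testing
adjustment is applied across tested frequencies; with eight frequencies
this is a caveat the user should keep in mind.

**Comparison statistics.** Band extremes are the intervals at the phases
where the center attains its minimum and maximum (earliest phase on ties).
The GSBB/VBPBB width ratio is summarised by the median and quartiles of
the per-phase ratio. `r_squared` is the squared Pearson correlation
between a filtered component and the raw series on their joint valid
region; note that for weak components it includes the in-band noise the
filter passes, so it is an upper bound on the component's own variance
share.

**Randomness.** Replicate `r` draws from a generator seeded by
`(seed, r)`, so bands are bit-identical under a fixed seed and replicate
sets are order-independent.

## Synthetic generator

`SyntheticSpec` defaults describe the emulated monitoring record: 99,825
hourly samples at a 20.57 ppb grand mean; a winter-high annual cosine
(period 8760 h, amplitude 6 ppb, peaking at t=0 on Jan 1); a daily cosine
(0.9 ppb) with a 12-hour second harmonic (0.6 ppb); a weekly cosine
(0.4 ppb); a centred linear trend of −3×10⁻⁵ ppb/h (≈ −0.26 ppb/yr);
Gaussian noise with σ = 8 ppb (optionally AR(1)); 5% sporadic missing
hours; and five coded-error readings. The daily/weekly amplitudes are an
order of magnitude below the annual one, matching the component scales a
narrow bandpass actually isolates from such records — at these scales the
pipeline reproduces the qualitative pattern of interest: only the annual
band is significant, the rest are not. Coded errors appear as sentinel
values with a qualifier code only in the written AQS-dialect file, so the
reader's cleaning path is exercised end-to-end.

Two truth oracles are provided: `true_periodic_mean` aggregates every term
that is periodic on the query grid (e.g. the daily cycle embedded in the
annual phase profile, and the exact phase-conditional trend offset), while
`true_component_deviation` returns only the cosine at exactly the query
period — the correct reference for what the bandpass filter isolates.

What the generator does **not** emulate: meteorology-driven variability
(wind, temperature), regime shifts (e.g. pandemic-era traffic changes),
heteroscedastic or skewed noise, and phase-drifting daily patterns. Tests
passing on this generator therefore demonstrate correctness of the
machinery and the qualitative precision/power ordering, not the numeric
values any particular real record would produce.

## Desk-scale conventions

Simulation-backed tests and the acceptance script shorten the "annual"
period to 720 samples with n = 20,000 (≈ 28 cycles, comparable cycle count
to 11 years of hourly data), keep daily/weekly periods and all amplitudes
at full-scale values, and use 100–1000 bootstrap replicates; the type-I
simulation uses 200 pure-noise series of 5,000 samples at period 100.
These sizes are the package's test convention; every operation accepts
full-scale inputs unchanged.

## Numerical choices

* Filter smoothing via FFT convolution (`scipy.signal.fftconvolve`);
  kernel weights by direct convolution (exact at these magnitudes).
* Periodogram: raw (boxcar, unsmoothed) one-sided estimate with
  `scaling="spectrum"`, mean-imputed missing values, zero-frequency term
  dropped; peak screening takes strict local maxima ranked by power, ties
  broken toward the lower frequency, with an optional `min_freq` to read
  the region past the low-frequency trend rise.
* Quantiles: linear interpolation throughout.
* Frequencies in the pipeline registry are exact rationals (cycles per
  hour) to avoid floating drift in phase arithmetic; periods are their
  rounded reciprocals, and the annual period is fixed at 8760 h (leap
  days are not modelled).
* Degenerate inputs: a constant component yields R² = 0 with a warning; a
  phase with no valid observation, a period exceeding the usable data, or
  an all-missing filter window raise informative errors; per-frequency
  failures inside the pipeline are isolated into error rows.

## Known limitations

* Pointwise percentile bands assembled into a band — no simultaneous
  (joint) coverage guarantee.
* The band width under the default construction reflects data spread, not
  the standard error of the periodic-mean estimate; use
  `band_type="mean"` for the latter, but not together with the
  horizontal-line rule (see above).
* No automatic selection of `m`, `k`, block length or replicate count.
* The AQS reader matches a single site by printed coordinates and treats
  any non-empty qualifier as a coded error; multi-site aggregation and
  unit conversion are out of scope.
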