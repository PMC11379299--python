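"""Periodic means, GSBB/VBPBB resampling, bands, significance, comparisons."""

import numpy as np
import pytest

from vbpbb import (
    BootstrapConfig,
    ConfidenceBand,
    FilterSpec,
    band_extremes,
    band_from_bootstrap,
    generate,
    gsbb_resample,
    periodic_mean,
    r_squared,
    read_band,
    significance,
    true_component_deviation,
    width_ratio,
    write_band,
)
from vbpbb.kzft import ComponentEstimate

from conftest import scaled_spec


def make_band(lower, center, upper, period=None, method="VBPBB"):
    lower, center, upper = map(np.asarray, (lower, center, upper))
    return ConfidenceBand(
        period=period or lower.size, lower=lower, center=center, upper=upper,
        method=method,
    )


class TestPeriodicMean:
    def test_simple_phase_means(self):
        dev = periodic_mean(np.array([1.0, 2, 3, 1, 2, 3]), 3)
        np.testing.assert_allclose(dev, [-1.0, 0.0, 1.0])

    def test_constant_series_zero_deviation(self):
        np.testing.assert_allclose(periodic_mean(np.full(20, 5.0), 4), 0.0, atol=1e-12)

    def test_phase_offset_rotates_assignment(self):
        x = np.array([1.0, 2, 3, 1, 2, 3])
        np.testing.assert_allclose(periodic_mean(x, 3, phase_offset=1), [1.0, -1.0, 0.0])

    def test_missing_values_ignored(self):
        x = np.array([1.0, 2, 3, np.nan, 2, 3])
        np.testing.assert_allclose(periodic_mean(x, 3), [-1.2, -0.2, 0.8])

    def test_empty_phase_raises_naming_phase(self):
        x = np.array([1.0, np.nan, 3, 1, np.nan, 3])
        with pytest.raises(ValueError, match="phase 1"):
            periodic_mean(x, 3)

    def test_period_below_two_rejected(self):
        with pytest.raises(ValueError):
            periodic_mean(np.arange(10.0), 1)


class TestGSBBResample:
    def test_whole_series_block_returns_original(self, rng):
        x = rng.normal(size=48)
        cfg = BootstrapConfig(n_boot=100, block_length=48, circular=False)
        np.testing.assert_array_equal(gsbb_resample(x, 12, cfg, rng), x)

    def test_period_one_is_ordinary_block_bootstrap(self, rng):
        x = np.arange(100.0)
        cfg = BootstrapConfig(n_boot=100, block_length=10)
        y = gsbb_resample(x, 1, cfg, rng)
        assert y.shape == x.shape
        assert set(y).issubset(set(x))
        # blocks are contiguous (circularly wrapping) runs of the original
        assert np.all(np.diff(y.reshape(10, 10), axis=1) % 100 == 1)

    @pytest.mark.parametrize("circular", [True, False])
    def test_exactly_periodic_series_invariant_phase_means(self, circular, rng):
        x = np.tile(np.array([4.0, -1.0, 0.5, 2.0, -3.0, 1.5]), 4)
        cfg = BootstrapConfig(n_boot=100, circular=circular)
        ref = periodic_mean(x, 6)
        for r in range(20):
            y = gsbb_resample(x, 6, cfg, np.random.default_rng(r))
            np.testing.assert_allclose(periodic_mean(y, 6), ref, atol=1e-12)

    def test_resample_preserves_phase_content(self, rng):
        # every resampled position holds a value observed at the same phase
        x = rng.normal(size=60) + 10 * (np.arange(60) % 5)
        y = gsbb_resample(x, 5, BootstrapConfig(n_boot=100), rng)
        for s in range(5):
            assert set(y[s::5]).issubset(set(x[s::5]))

    def test_period_longer_than_series_rejected(self, rng):
        with pytest.raises(ValueError):
            gsbb_resample(np.arange(10.0), 20, BootstrapConfig(n_boot=100), rng)


class TestBandFromBootstrap:
    def test_deterministic_given_seed(self):
        x = np.random.default_rng(7).normal(size=600)
        cfg = BootstrapConfig(n_boot=120, seed=42)
        b1 = band_from_bootstrap(x, 12, cfg)
        b2 = band_from_bootstrap(x, 12, cfg)
        np.testing.assert_array_equal(b1.lower, b2.lower)
        np.testing.assert_array_equal(b1.upper, b2.upper)
        np.testing.assert_array_equal(b1.center, b2.center)

    def test_noise_free_sinusoid_vbpbb_band_degenerates(self):
        d = 24
        t = np.arange(4000)
        x = 3.0 * np.cos(2 * np.pi * t / d)
        spec = FilterSpec.from_period(d)
        band = band_from_bootstrap(
            x, d, BootstrapConfig(n_boot=100, seed=0), method="VBPBB", spec=spec
        )
        assert band.width.max() < 1e-6
        np.testing.assert_allclose(
            band.center, 3.0 * np.cos(2 * np.pi * np.arange(d) / d), atol=0.02
        )

    def test_alpha_nesting(self):
        x = np.random.default_rng(3).normal(size=1200)
        kwargs = dict(n_boot=300, seed=5)
        wide = band_from_bootstrap(x, 12, BootstrapConfig(alpha=0.05, **kwargs))
        narrow = band_from_bootstrap(x, 12, BootstrapConfig(alpha=0.5, **kwargs))
        assert np.all(narrow.lower >= wide.lower - 1e-12)
        assert np.all(narrow.upper <= wide.upper + 1e-12)
        assert np.mean((narrow.lower > wide.lower) & (narrow.upper < wide.upper)) > 0.9

    def test_mean_band_is_narrower_than_value_band(self):
        x = np.random.default_rng(9).normal(size=2400)
        value = band_from_bootstrap(x, 12, BootstrapConfig(n_boot=200, seed=1))
        mean = band_from_bootstrap(
            x, 12, BootstrapConfig(n_boot=200, seed=1, band_type="mean")
        )
        assert np.all(mean.width < value.width)

    def test_vbpbb_requires_spec(self):
        with pytest.raises(ValueError, match="FilterSpec"):
            band_from_bootstrap(
                np.ones(100), 10, BootstrapConfig(n_boot=100), method="VBPBB"
            )

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError, match="n_boot"):
            band_from_bootstrap(np.ones(100), 10, BootstrapConfig(n_boot=50))

    def test_insufficient_data_after_filtering_rejected(self):
        spec = FilterSpec.from_period(50)  # half-width 100 swallows the series
        with pytest.raises(ValueError):
            band_from_bootstrap(
                np.random.default_rng(0).normal(size=260), 50,
                BootstrapConfig(n_boot=100), method="VBPBB", spec=spec,
            )

    def test_vbpbb_narrower_than_gsbb_on_synthetic(self, desk_series):
        series, _ = desk_series
        cfg = BootstrapConfig(n_boot=150, seed=2)
        spec = FilterSpec.from_period(720)
        v = band_from_bootstrap(series, 720, cfg, method="VBPBB", spec=spec)
        g = band_from_bootstrap(series, 720, cfg, method="GSBB")
        assert np.mean(v.width < g.width) >= 0.95

    def test_vbpbb_center_tracks_truth(self):
        spec_syn = scaled_spec(n=12_000, seed=21)
        series, _ = generate(spec_syn)
        band = band_from_bootstrap(
            series, 720, BootstrapConfig(n_boot=100, seed=3),
            method="VBPBB", spec=FilterSpec.from_period(720),
        )
        # the bandpass isolates only the 720-sample component, so compare
        # against its own deviation, not the full periodic mean (which also
        # carries the embedded daily cycle)
        truth = true_component_deviation(spec_syn, 720)
        rmse = np.sqrt(np.mean((band.center - truth) ** 2))
        assert rmse <= 0.15 * 6.0
        # and the band covers the truth almost everywhere
        covered = (band.lower <= truth) & (truth <= band.upper)
        assert covered.mean() >= 0.90


class TestSignificance:
    def test_band_without_horizontal_line_is_significant(self):
        band = make_band([-1, 2], [-0.5, 2.5], [0, 3])
        res = significance(band)
        assert res.significant
        assert res.pct_excluding_zero == pytest.approx(50.0)

    def test_band_admitting_zero_line_is_not_significant(self):
        band = make_band([-1, -1], [0, 0], [1, 1])
        res = significance(band)
        assert not res.significant
        assert res.pct_excluding_zero == 0.0

    def test_flat_noise_rarely_fires(self):
        fires = 0
        for r in range(20):
            x = np.random.default_rng(100 + r).normal(size=1500)
            band = band_from_bootstrap(
                x, 50, BootstrapConfig(n_boot=150, seed=r), method="VBPBB",
                spec=FilterSpec.from_period(50),
            )
            fires += significance(band).significant
        assert fires <= 1


class TestBandExtremes:
    def test_extreme_center_phases(self):
        band = make_band([-3, -1, 4], [-2, 0, 5], [-1, 1, 6])
        min_range, max_range = band_extremes(band)
        assert min_range == (-3.0, -1.0)
        assert max_range == (4.0, 6.0)

    def test_constant_center_ties_to_first_phase(self):
        band = make_band([-1, -2, -3], [0, 0, 0], [1, 2, 3])
        min_range, max_range = band_extremes(band)
        assert min_range == (-1.0, 1.0)
        assert max_range == (-1.0, 1.0)

    def test_sinusoid_extremes_half_period_apart(self):
        d = 36
        c = np.cos(2 * np.pi * np.arange(d) / d)
        band = make_band(c - 0.1, c, c + 0.1, period=d)
        assert np.argmin(band.center) - np.argmax(band.center) == d // 2


class TestWidthRatio:
    def test_elementwise_ratio_median(self):
        g = make_band([0, 0], [2, 3], [4, 6])
        v = make_band([1.5, 2], [2, 3], [2.5, 4])
        res = width_ratio(g, v)
        assert res.median == pytest.approx(3.5)
        assert res.q25 == pytest.approx(3.25)
        assert res.q75 == pytest.approx(3.75)

    def test_identical_bands_ratio_one(self):
        b = make_band([0, 0], [1, 1], [2, 2])
        assert width_ratio(b, b).median == pytest.approx(1.0)

    def test_zero_width_vbpbb_rejected(self):
        g = make_band([0, 0], [1, 1], [2, 2])
        v = make_band([1, 1], [1, 1], [1, 1])
        with pytest.raises(ValueError, match="degenerate"):
            width_ratio(g, v)

    def test_mismatched_periods_rejected(self):
        g = make_band([0, 0], [1, 1], [2, 2])
        v = make_band([0, 0, 0], [1, 1, 1], [2, 2, 2])
        with pytest.raises(ValueError, match="period"):
            width_ratio(g, v)


class TestRSquared:
    def _component(self, values, spec=None):
        spec = spec or FilterSpec(nu=0.1, m=3, k=1)
        return ComponentEstimate(
            values=np.asarray(values, float),
            valid_mask=np.isfinite(values), spec=spec,
        )

    def test_demeaned_copy_explains_everything(self, rng):
        x = rng.normal(size=500)
        comp = self._component(x - x.mean())
        assert r_squared(comp, x) == pytest.approx(1.0)

    def test_orthogonal_sinusoid_explains_nothing(self):
        t = np.arange(2400)
        x = np.cos(2 * np.pi * t / 24)
        comp = self._component(np.cos(2 * np.pi * t / 37.5))
        assert r_squared(comp, x) < 0.01

    def test_constant_component_warns_and_returns_zero(self, rng):
        comp = self._component(np.full(100, 2.0))
        with pytest.warns(UserWarning, match="constant"):
            assert r_squared(comp, rng.normal(size=100)) == 0.0

    def test_variance_fraction_recovered(self):
        spec_syn = scaled_spec(seed=33)
        series, _ = generate(spec_syn)
        comp_spec = FilterSpec.from_period(720)
        from vbpbb import bandpass

        comp = bandpass(series, comp_spec)
        r2 = r_squared(comp, series)
        # annual variance fraction: (6^2/2) / total ~ 0.215
        var_annual = 6.0**2 / 2
        var_total = var_annual + 0.9**2 / 2 + 0.6**2 / 2 + 0.4**2 / 2 + 8.0**2
        assert r2 == pytest.approx(var_annual / var_total, abs=0.04)


class TestBandIO:
    def test_csv_round_trip(self, tmp_path):
        x = np.random.default_rng(11).normal(size=600)
        band = band_from_bootstrap(x, 12, BootstrapConfig(n_boot=100, seed=0))
        path = tmp_path / "band.csv"
        write_band(band, path)
        back = read_band(path)
        assert back.period == band.period
        assert back.method == band.method
        np.testing.assert_allclose(back.lower, band.lower, atol=1e-6)
        np.testing.assert_allclose(back.center, band.center, atol=1e-6)
        np.testing.assert_allclose(back.upper, band.upper, atol=1e-6)
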