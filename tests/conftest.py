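import numpy as np
import pytest

from vbpbb import Component, HarmonicTerm, SyntheticSpec, generate


def scaled_spec(**overrides) -> SyntheticSpec:
    """Desk-scale study conditions: the annual cycle is shortened to a
    720-sample period so that ~28 cycles fit in 20,000 samples; daily and
    weekly periods and all amplitudes keep their full-scale values."""
    kwargs = dict(
        n=20_000,
        grand_mean=20.57,
        trend_slope=-3e-5,
        components=(
            Component(period=720.0, amplitude=6.0),
            Component(period=24.0, amplitude=0.9,
                      harmonics=(HarmonicTerm(multiple=2, amplitude=0.6),)),
            Component(period=168.0, amplitude=0.4),
        ),
        noise_sd=8.0,
        missing_rate=0.02,
        n_coded_errors=3,
        seed=11,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


@pytest.fixture(scope="session")
def desk_spec() -> SyntheticSpec:
    return scaled_spec()


@pytest.fixture(scope="session")
def desk_series(desk_spec):
    series, truth = generate(desk_spec)
    return series, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
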