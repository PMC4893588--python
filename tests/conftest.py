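"""Shared fixtures: small synthetic traces used across the suite."""

import numpy as np
import pytest

from greycast import GlucoseSeries, generate_day72h, generate_exact_grey, generate_postprandial


@pytest.fixture(scope="session")
def postprandial_series() -> GlucoseSeries:
    """24-sample 2-h post-meal window, seed 7 (the canonical fixture)."""
    return generate_postprandial(n=24, baseline=6.0, amplitude=8.0, seed=7, noise_sd=0.05)


@pytest.fixture(scope="session")
def exact_grey_series() -> GlucoseSeries:
    """Noise-free trace generated by the grey time response itself."""
    return generate_exact_grey(n=24, a=-0.02, b=1.8948, y0=float(np.log(7.0)))


@pytest.fixture(scope="session")
def day_trace() -> GlucoseSeries:
    """Seeded 72-h trace: 864 samples, three meals a day, AR(1) noise."""
    return generate_day72h(seed=123)


@pytest.fixture
def constant_series() -> GlucoseSeries:
    return GlucoseSeries([8.0] * 30)
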