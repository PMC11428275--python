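import numpy as np
import pytest

import herbwue as h


@pytest.fixture(scope="session")
def atmosphere():
    """Bundled 1927-2015 atmosphere table."""
    return h.read_atmosphere_series()


@pytest.fixture(scope="session")
def community(atmosphere):
    """Default five-species synthetic community at the canonical seed."""
    return h.generate_community(atmosphere=atmosphere, seed=0)


@pytest.fixture(scope="session")
def vcmax_model():
    """Trait model fitted on the default synthetic calibration campaign."""
    return h.fit_vcmax_model(h.generate_vcmax_training(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_atmosphere():
    """Single-year fixture series: 2015 at 400 ppm, -8.4 permil."""
    return h.AtmosphereSeries([2015], [400.0], [-8.4])
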