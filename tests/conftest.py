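import numpy as np
import pytest

from contourfill import RunConfig


@pytest.fixture(scope="session")
def config():
    """Default model configuration used across the suite."""
    return RunConfig()


@pytest.fixture(scope="session")
def fast_config():
    """Small-grid, short-movie configuration for unit-level pipeline tests."""
    return RunConfig(px_per_deg=5.0, battery_px_per_deg=4.0,
                     adapt_duration_outline=1.0, adapt_duration_flicker=1.0,
                     test_duration=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
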