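import numpy as np
import pytest

from pafscreen.config import PipelineConfig
from pafscreen.synthetic import DEFAULT_NORMAL, synth_record


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_record():
    """A 60 s noiseless synthetic record with ground truth."""
    return synth_record(
        "fix060", "normal", DEFAULT_NORMAL, duration_s=60.0, noise_sd_mv=0.0, seed=7
    )


@pytest.fixture(scope="session")
def medium_record():
    """A 300 s synthetic record (enough beats for every HRV block)."""
    return synth_record(
        "fix300", "normal", DEFAULT_NORMAL, duration_s=300.0, noise_sd_mv=0.01, seed=11
    )


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline config with a lighter HTGA budget for unit tests."""
    return PipelineConfig(
        htga_population_size=30, htga_generations=40, max_fitted_beats=8
    )
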