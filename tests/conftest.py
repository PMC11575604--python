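import numpy as np
import pytest
from hypothesis import settings

from echoshift import AcquisitionParams, ParameterRanges

# keep hypothesis reproducible in CI-less environments
settings.register_profile("default", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("default")


@pytest.fixture(scope="session")
def acq():
    """Full-size acquisition: 4096 points, 4096 Hz, 8 echoes, 1 Hz/point."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def acq_small():
    """Reduced grid (1024 points at 1 Hz/point) for fast simulations."""
    return AcquisitionParams(np_points=1024, sw_hz=1024.0)


@pytest.fixture(scope="session")
def easy_ranges():
    """Noise-light sampling ranges for fixtures that probe the pipeline."""
    return ParameterRanges(
        n_signals=(1, 5), wsn=(50.0, 200.0), solvent_fraction=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
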