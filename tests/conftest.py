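import numpy as np
import pytest

from cardiobeat.synthetic_data import SyntheticWellSpec, generate_well_video


@pytest.fixture(scope="session")
def short_beating_video():
    """A 4-s synthetic beating well at 1.5 beats/s (seed 7) + ground truth."""
    spec = SyntheticWellSpec(frequency=1.5, duration=4.0, seed=7)
    return generate_well_video(spec)


@pytest.fixture(scope="session")
def static_video():
    """A synthetic well with zero contraction amplitude."""
    spec = SyntheticWellSpec(frequency=1.5, amplitude=0.0, duration=3.0, seed=7)
    return generate_well_video(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
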