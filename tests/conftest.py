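import numpy as np
import pytest

from cspselect import SimConfig, generate_session


@pytest.fixture(scope="session")
def strong_session():
    """Clean, strongly separable session: variance contrast on C3/C4."""
    return generate_session(
        SimConfig(
            seed=42, effect=8.0, n_trials_per_class=100,
            disc_channels=("C3", "C4"), mixing_strength=0.0,
        )
    )


@pytest.fixture(scope="session")
def null_session():
    """No class contrast at all: both classes share one distribution."""
    return generate_session(
        SimConfig(seed=43, effect=1.0, n_trials_per_class=100)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
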