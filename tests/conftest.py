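import numpy as np
import pytest

from traffickpk import TraffickingScenario


@pytest.fixture
def rng():
    return np.random.default_rng(20120231)


@pytest.fixture
def noise_free_scenario():
    """A scenario with every stochastic layer off (exact round trips)."""
    return TraffickingScenario(biological_cv=0.0, counting_noise=False, seed=7)


@pytest.fixture
def default_scenario():
    return TraffickingScenario(seed=7)
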