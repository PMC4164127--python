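import numpy as np
import pytest

from twoldm import ExWaldParams, SynthConfig, generate_likelihood


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return ExWaldParams(v=1.0, s=1.0, theta=1.0, gamma=0.2)


@pytest.fixture
def default_series():
    return generate_likelihood(SynthConfig(seed=1))


def random_valid_params(rng, n_sets):
    """Draw valid ex-Wald parameter sets (real-k region) for property tests."""
    out = []
    while len(out) < n_sets:
        v = rng.uniform(0.5, 2.0)
        s = rng.uniform(0.5, 2.0)
        theta = rng.uniform(0.5, 3.0)
        gamma = rng.uniform(0.05, 0.4)
        if v**2 >= 2.0 * gamma * s**2:
            out.append(ExWaldParams(v=v, s=s, theta=theta, gamma=gamma))
    return out
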