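import numpy as np
import pytest

from fontan_listing import ModelParams, compute_thresholds, sample_valid_params


@pytest.fixture(scope="session")
def example_params():
    """The package's worked example: mu=2/yr, theta=0.8, r=0.1/yr,
    delta=0.5y, LT=10y, LNT=2y."""
    return ModelParams(mu=2.0, theta=0.8, r=0.1, delta=0.5, lt=10.0, lnt=2.0)


@pytest.fixture(scope="session")
def example_thresholds(example_params):
    return compute_thresholds(example_params)


@pytest.fixture(scope="session")
def random_param_sets():
    """20 seeded clinically-plausible valid parameter sets."""
    rng = np.random.default_rng(20250920)
    return [sample_valid_params(rng) for _ in range(20)]
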