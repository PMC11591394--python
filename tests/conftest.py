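import numpy as np
import pytest

from owlitr import SyntheticConfig, generate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20240993)


@pytest.fixture(scope="session")
def default_trial():
    """One default-configuration trial draw (n = 122), session-cached."""
    return generate_trial(SyntheticConfig(n=122, seed=11))


@pytest.fixture(scope="session")
def big_covariate_sample():
    """A 10,000-row covariate draw for moment checks, session-cached."""
    from owlitr import generate_covariates
    cfg = SyntheticConfig(n=10_000)
    return generate_covariates(cfg, np.random.default_rng(77)), cfg
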