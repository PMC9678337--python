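import numpy as np
import pytest

from hgtstab import ModelParams, generate_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    """Headline parameter set (10 taxa, connectance 0.7, mixed interactions)."""
    return ModelParams()


@pytest.fixture
def noninteracting_params():
    return ModelParams(C=0.0)


@pytest.fixture
def community(params):
    return generate_ensemble(params, 1, 7)[0]


@pytest.fixture
def noninteracting_community(noninteracting_params):
    return generate_ensemble(noninteracting_params, 1, 7)[0]
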