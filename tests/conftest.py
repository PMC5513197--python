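import numpy as np
import pytest

from expobench import GeneratorConfig, build_correlation_model


@pytest.fixture(scope="session")
def default_model():
    """The calibrated 237-exposure correlation model (seed 1)."""
    return build_correlation_model(GeneratorConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
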