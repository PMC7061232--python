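import numpy as np
import pytest

from tasti.model import Configuration, ModelParameters


@pytest.fixture
def canon_config() -> Configuration:
    """Species tree ((A,B),C) with B sharing the outgroup's deme."""
    return Configuration(("A", "B", "C"), shared="B")


@pytest.fixture
def omega_m5(canon_config) -> ModelParameters:
    """The M=5 simulation-study setting with the longer internal branch."""
    return ModelParameters.symmetric(canon_config, 2.5e-3, 5.25e-3, 0.005, 5.0, 5e4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
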