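import numpy as np
import pytest

from polyqmd.constructs import build_construct
from polyqmd.dmd import ChainSystem


@pytest.fixture(scope="session")
def q8_system() -> ChainSystem:
    return ChainSystem.from_model(build_construct("QN", 8))


@pytest.fixture(scope="session")
def q4_system() -> ChainSystem:
    return ChainSystem.from_model(build_construct("QN", 4))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
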