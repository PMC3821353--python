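import numpy as np
import pytest

from veinmap import CodePopulationSpec, generate_code_population
from veinmap.features import BinaryCode


@pytest.fixture
def rng():
    return np.random.default_rng(20130912)


@pytest.fixture
def random_codes(rng):
    """Factory: k random codes of one length sharing a tag."""

    def make(k=5, length=64, tag="lbp"):
        return [
            BinaryCode.from_bits(rng.integers(0, 2, length), tag) for _ in range(k)
        ]

    return make


@pytest.fixture(scope="session")
def desk_population():
    """The default heterogeneous-stability code gallery (20 classes x 16)."""
    return generate_code_population(CodePopulationSpec(seed=20130912))
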