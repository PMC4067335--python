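import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20140623)
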