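import numpy as np
import pytest

from comotif.conservation import AlignmentParams


@pytest.fixture
def params() -> AlignmentParams:
    return AlignmentParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
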