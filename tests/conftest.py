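import numpy as np
import pytest

from tadstruct.hic_io import BinIndex, ContactMatrix
from tadstruct.synthetic import SyntheticSpec, make_structure, structure_to_contacts


@pytest.fixture
def helix10():
    return make_structure(SyntheticSpec("helix", 10))


@pytest.fixture
def helix10_contacts(helix10):
    return structure_to_contacts(helix10)


@pytest.fixture
def small_matrix():
    counts = np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 4.0], [1.0, 4.0, 0.0]])
    return ContactMatrix(counts, BinIndex(40_000, "chr1"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
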