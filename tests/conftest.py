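import numpy as np
import pytest

from bpmedian import GenomeClass, Permutation


@pytest.fixture
def id6():
    return GenomeClass(Permutation(range(1, 7)))


@pytest.fixture
def interleaved6():
    """The six-gene genome at maximum distance 5 from the identity."""
    return GenomeClass(Permutation.from_string("1 3 5 2 4 6"))


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20240917))


def random_perm(n, rng):
    return Permutation(rng.permutation(n) + 1)
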