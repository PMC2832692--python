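import numpy as np
import pytest

import nullvec as nv


@pytest.fixture(scope="session")
def codon61():
    return nv.codon_prior("codons_over_61")


@pytest.fixture(scope="session")
def codon64():
    return nv.codon_prior("codons_over_64")


@pytest.fixture
def gaga():
    return nv.SequenceRecord("a", "GAGA")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, n):
    return "".join(rng.choice(list(nv.PROTEIN.symbols), size=n))
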