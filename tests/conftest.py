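import pytest

from capriq.structure_io import build_correspondence
from capriq.synthetic import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def c2_dimer():
    """Default C2 homodimer toy complex (2 x 20 residues)."""
    return make_toy_complex(ToyComplexSpec())


@pytest.fixture(scope="session")
def c3_trimer():
    return make_toy_complex(
        ToyComplexSpec(n_chains=3, chain_lengths=(20, 20, 20), symmetry="C3")
    )


@pytest.fixture(scope="session")
def hetero_dimer():
    return make_toy_complex(
        ToyComplexSpec(n_chains=2, chain_lengths=(24, 18), symmetry="none", hetero=True)
    )


@pytest.fixture
def identity_corr(c2_dimer):
    return build_correspondence(c2_dimer, c2_dimer, {"A": "A", "B": "B"})
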