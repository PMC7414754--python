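import numpy as np
import pytest

from v1r_clade_evo.datasets import default_species_tree


@pytest.fixture
def species_tree():
    return default_species_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
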