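import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20220516)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
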