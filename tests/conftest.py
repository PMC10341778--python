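import random

import numpy as np
import pytest
from hypothesis import settings

from glysite.core import GlycanComposition, ProteinSequence

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20230613)


@pytest.fixture
def random_sequences():
    """Deterministic batch of random canonical protein sequences."""

    def make(n, min_len=5, max_len=60, seed=0):
        r = random.Random(seed)
        return [
            "".join(r.choices(AMINO_ACIDS, k=r.randint(min_len, max_len)))
            for _ in range(n)
        ]

    return make


@pytest.fixture
def random_compositions():
    def make(n, seed=0):
        r = random.Random(seed)
        return [
            GlycanComposition(
                hexnac=r.randint(0, 8),
                hex=r.randint(0, 12),
                fuc=r.randint(0, 3),
                neuac=r.randint(0, 4),
                neugc=r.randint(0, 2),
            )
            for _ in range(n)
        ]

    return make


@pytest.fixture
def small_protein():
    # one sequon (N at 5) on a tryptic peptide, Cys to exercise the fixed mod
    return ProteinSequence(id="toy", residues="AGKDCNGTVLRGGAK")
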