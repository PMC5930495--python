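import numpy as np
import pytest

from deamotif import CodingSequence, SyntheticSpec, random_cds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_cds():
    """Factory for seeded random coding sequences."""

    def _make(n_codons=60, gc3=0.5, seed=0):
        return random_cds(SyntheticSpec(n_codons=n_codons, gc3=gc3, seed=seed))

    return _make


@pytest.fixture
def ile_glu_seq():
    """Ile + Glu + Phe: one H-, one R- and one Y-class codon."""
    return CodingSequence("ATTGAATTC", "toy")
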