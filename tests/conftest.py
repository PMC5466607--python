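import numpy as np
import pytest

from polyexpress.band_matrix import BandMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20170609)


@pytest.fixture
def random_dna(rng):
    def make(length: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=length))

    return make


@pytest.fixture
def small_matrix():
    """Four bands x three taxa x two replicates with known reconciliations."""
    keys = [("E-AGC/M-CAC", 250), ("E-AGC/M-CAC", 180),
            ("E-ACG/M-CAA", 320), ("E-ACG/M-CAA", 140)]
    lanes = {
        "GA.1": [2, 2, 0, 1],
        "GA.2": [2, 0, 0, 1],
        "AS.1": [1, 1, 2, 1],
        "AS.2": [1, 1, 2, 1],
        "GS.1": [0, 3, 2, 1],
        "GS.2": [0, 3, 1, 1],
    }
    return BandMatrix.from_lanes(keys, lanes)
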