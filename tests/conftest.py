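import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from fertpred._tables import AMINO_ACIDS
from fertpred.sequence_io import ProteinSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, length, ident="seq"):
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinSequence(id=ident, residues=residues)


@pytest.fixture
def make_protein():
    return random_protein
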