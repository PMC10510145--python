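import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dtakit.chem import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, smiles_to_graph
from dtakit.mol_encoder import MolEncoder


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_encoder(rng):
    """Depth-3 encoder at test width d=8, dropout off."""
    return MolEncoder(rng, ATOM_FEATURE_DIM, BOND_FEATURE_DIM,
                      hidden_dim=8, depth=3, dropout_rate=0.0)


@pytest.fixture
def cyclopropane():
    return smiles_to_graph("C1CC1")


@pytest.fixture
def propane():
    return smiles_to_graph("CCC")
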