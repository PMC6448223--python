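import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from scaffoldkit import make_toy_protein


@pytest.fixture
def toy():
    """12-residue poly-alanine toy chain (60 atoms)."""
    return make_toy_protein(12, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
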