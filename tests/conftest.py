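import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from glycofp import MolecularSystem
from glycofp.synthetic import make_planted_complex, make_toy_disaccharide


@pytest.fixture(scope="session")
def disaccharide_system() -> MolecularSystem:
    gcu, nag = make_toy_disaccharide()
    return MolecularSystem([gcu, nag])


@pytest.fixture(scope="session")
def planted_one_each():
    """One planted event of every type, no decoys, fixed seed."""
    return make_planted_complex(1, 1, 1, 1, "CA", 1, 0, seed=7)
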