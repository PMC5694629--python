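import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cyanotax import signatures as sig
from cyanotax import synthetic as syn


@pytest.fixture(scope="session")
def clade_scene():
    """Default planted clade: 3 genera x 2 species x 2 genomes."""
    return syn.make_clade(seed=11)


@pytest.fixture(scope="session")
def clade_matrices(clade_scene):
    """Signature matrices for the default clade (shared; ~20 s to build)."""
    return sig.compute_signature_matrices(
        clade_scene.proteomes, clade_scene.genomes, clade_scene.s16)
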