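import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import morphoclad as mc
from morphoclad.matrix import CharacterMatrix


@pytest.fixture(scope="session")
def aphrodini():
    return mc.load_aphrodini_matrix()


@pytest.fixture(scope="session")
def aphrodini_mp(aphrodini):
    """A heuristic MP search of the packaged matrix (cached per session)."""
    return mc.heuristic_search(aphrodini, replicates=100, trees_to_save=50, seed=0)


@pytest.fixture(scope="session")
def planaphrodes_taxa():
    roles = mc.load_taxon_roles()
    return [t for t, r in roles.items() if r == "ingroup"]


def random_matrix(rng, n_taxa, n_chars, n_states=2, p_missing=0.0):
    states = rng.integers(0, n_states, size=(n_taxa, n_chars)).astype(np.int8)
    if p_missing:
        mask = rng.uniform(size=states.shape) < p_missing
        states[mask] = -1
    return CharacterMatrix([f"t{i}" for i in range(n_taxa)], states)
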