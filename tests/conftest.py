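import numpy as np
import pandas as pd
import pytest

from molcloud import Structure
from molcloud.fixtures import ToySpec, make_toy_polymer


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def three_atom_structure():
    """CA/CB/CA triple used by selection tests."""
    meta = pd.DataFrame({
        "atom_name": ["CA", "CB", "CA"],
        "residue_id": [1, 1, 2],
        "chain_id": ["A", "A", "A"],
        "element": ["C", "C", "C"],
    })
    coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
    return Structure(coords, meta)


@pytest.fixture
def toy_polymer():
    return make_toy_polymer(ToySpec(n_residues=10, geometry="helix"))


@pytest.fixture
def random_cloud(rng):
    def make(n=5, m=1, scale=10.0, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return Structure(r.normal(scale=scale, size=(m, n, 3)))
    return make


def random_rotation(rng):
    """Uniform proper rotation via QR with sign fix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
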