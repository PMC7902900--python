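import numpy as np
import pytest

import mdpost as mp


@pytest.fixture
def toy_topology():
    """5-residue single-chain toy system with one CA-like atom per residue."""
    return mp.build_toy_system(mp.SyntheticSpec(n_residues=5, seed=0))


@pytest.fixture
def toy_complex():
    """Three-atom complex: two-residue receptor (chain A) + one-residue ligand
    (chain B), with charges chosen so every energy term is nonzero."""
    spec = mp.SyntheticSpec(
        chain_layout=[("A", 2), ("B", 1)],
        n_residues=3,
        charges=np.array([0.5, -0.5, 0.3]),
        seed=0,
    )
    top = mp.build_toy_system(spec)
    coords = np.array([[[0.0, 0, 0], [4.0, 0, 0], [2.0, 4, 0]]])
    return mp.Trajectory(top, coords)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
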