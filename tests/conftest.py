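import numpy as np
import pytest

import memperm as mp
from memperm.core import SelectionSpec, select


@pytest.fixture(scope="session")
def bilayer_with_solutes():
    """Full-size synthetic bilayer (64 lipids/leaflet, 200 frames) with DBP solutes."""
    bparams = mp.BilayerParams(seed=11)
    sparams = mp.SoluteParams(n_solutes=4, species="DBP", dz_mean=12.0, dz_width=1.0, seed=11)
    traj, truth = mp.generate_bilayer_trajectory(bparams, sparams)
    return traj, truth, bparams, sparams


@pytest.fixture(scope="session")
def small_bilayer():
    """Small, fast bilayer for structural/selection tests."""
    bparams = mp.BilayerParams(lipids_per_leaflet=16, n_frames=20, seed=7)
    traj, truth = mp.generate_bilayer_trajectory(bparams)
    return traj, truth


@pytest.fixture
def p_selection():
    return lambda traj: select(traj.topology, SelectionSpec(role_tags=["lipid_P"]))


@pytest.fixture(scope="session")
def flat_frame():
    """One frame with a handful of free atoms in a 20 Å box, for geometry tests."""
    atoms = [
        mp.AtomRecord("X1", "ION", i + 1, 1.0, frozenset({"ion"})) for i in range(4)
    ]
    mols = [mp.Molecule(i, i + 1, "ion") for i in range(4)]
    top = mp.Topology(atoms, mols)
    pos = np.zeros((4, 3))
    return top, pos
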