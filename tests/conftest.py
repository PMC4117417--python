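import numpy as np
import pytest

from allodyn import synth, topology as tp


@pytest.fixture(scope="session")
def helix60():
    """Small helical poly-alanine system shared across tests."""
    top, mean = synth.helix_mean_structure(60)
    return top, mean


@pytest.fixture(scope="session")
def planted_traj():
    """Planted-structure ensemble (blocks, loops, fiber), one seed."""
    spec, truth = synth.planted_study_spec(n_residues=150, n_frames=600,
                                           seed=11)
    return synth.sample_gaussian_trajectory(spec), spec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def ca_selection(top):
    first, last = int(top.residues[0]), int(top.residues[-1])
    return tp.select(top, [(first, last)], {"CA"})
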