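import numpy as np
import pytest

from fepath.potentials import double_well_1d, harmonic_nd, muller_brown
from fepath.toy_systems import make_toy_complex


@pytest.fixture(scope="session")
def mb():
    return muller_brown()


@pytest.fixture(scope="session")
def dwell():
    return double_well_1d(5.0)


@pytest.fixture(scope="session")
def harm2d():
    return harmonic_nd([2.0, 3.0], center=[0.5, -1.0])


@pytest.fixture()
def toy_complex():
    return make_toy_complex(
        6, atoms_per_residue=3, seed=11, neutral_residues=False, n_solvent=8
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
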