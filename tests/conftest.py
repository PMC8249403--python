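import numpy as np
import pytest

from cryobife.benchmarks import make_toy_rotor, toy_rotor_path
from cryobife.path import Conformation, GroundTruthProfile, make_path


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def rotor_path():
    """Small toy-rotor path shared by likelihood/benchmark tests."""
    return toy_rotor_path(4, 12, 25.0)


@pytest.fixture()
def single_bead():
    return Conformation(
        bead_positions=np.zeros((1, 3)),
        bead_radii=np.array([5.0]),
        bead_electrons=np.array([100.0]),
    )


@pytest.fixture()
def flat_profile_4():
    return GroundTruthProfile.tabulated(np.zeros(4))
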