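import numpy as np
import pytest

from mirclock import integrate, load_parameters, sensitivity_matrix
from mirclock.simulate import SimulationSettings


@pytest.fixture(scope="session")
def set3():
    return load_parameters("Set3")


@pytest.fixture(scope="session")
def set1():
    return load_parameters("Set1")


@pytest.fixture(scope="session")
def basal_traj(set3):
    """Basal (coupling-on) trajectory: 500 h, 200 h transient discard."""
    return integrate(set3, SimulationSettings(t_end=500.0))


@pytest.fixture(scope="session")
def uncoupled_traj(set1):
    """Same conditions with the silencing-complex formation off (C3 = 0)."""
    return integrate(set1, SimulationSettings(t_end=500.0))


@pytest.fixture(scope="session")
def smat(set3):
    """Full 49 x 76 scaled-sensitivity matrix at the basal set (~2 min)."""
    return sensitivity_matrix(set3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
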