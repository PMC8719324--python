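import numpy as np
import pytest

import qclines as q


@pytest.fixture(scope="session")
def dimer_fixture():
    """Default dimer study conditions: (system, spectral density, T)."""
    return q.dimer_default()


@pytest.fixture(scope="session")
def fmo7():
    return q.build_fmo(7)


@pytest.fixture(scope="session")
def fmo8():
    return q.build_fmo(8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def monomer():
    """Single-site system with unit dipole, used for analytic limits."""
    return q.ExcitonSystem(site_energies=np.array([100.0]),
                           couplings=np.zeros((1, 1)),
                           dipoles=np.array([[1.0, 0.0, 0.0]]))


@pytest.fixture(scope="session")
def zero_bath():
    """A decoupled bath (lambda = 0)."""
    sd = q.SpectralDensityParams(kind="debye", lam=0.0, gamma_fs=100.0)
    return q.discretize_bath(sd, 4, 1)
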