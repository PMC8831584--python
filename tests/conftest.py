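import numpy as np
import pytest

from optvdw.geometry import make_benzene, make_dimer
from optvdw.parameters import QDOParams, load_parameters


@pytest.fixture(scope="session")
def h_params():
    """Hydrogen free-atom QDO parameters (alpha0 = 4.5 bohr^3)."""
    return load_parameters(["H", "H"])


@pytest.fixture(scope="session")
def h_alpha_omega(h_params):
    return float(h_params.alpha0[0]), float(h_params.omega[0])


@pytest.fixture(scope="session")
def benzene_params():
    return load_parameters(make_benzene().elements)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
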