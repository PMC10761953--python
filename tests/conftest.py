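import numpy as np
import pytest

import prspath as pp


@pytest.fixture(scope="session")
def helix20():
    return pp.make_helix(20)


@pytest.fixture(scope="session")
def helix_network(helix20):
    return pp.build_anm_hessian(helix20, cutoff_rc=13.0)


@pytest.fixture(scope="session")
def helix_cov(helix_network):
    return pp.anm_covariance(helix_network)


@pytest.fixture(scope="session")
def dumbbell():
    """Deterministic two-domain fixture with its ground-truth channel."""
    model, channel = pp.make_dumbbell(10, 3, seed=1)
    return model, channel


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
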