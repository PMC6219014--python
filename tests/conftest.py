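import numpy as np
import pytest

import taview as tv


@pytest.fixture(scope="session")
def heart():
    return tv.build_synthetic_heart(64, 60, 60.0)


@pytest.fixture(scope="session")
def torso():
    return tv.build_synthetic_torso(200, 300.0)


@pytest.fixture(scope="session")
def electrodes(torso):
    return tv.place_standard_electrodes(torso)


@pytest.fixture(scope="session")
def leadfield_fine(heart, torso, electrodes):
    return tv.compute_transfer_matrix(heart, torso, electrodes)


@pytest.fixture(scope="session")
def small_bundle():
    """The default 20-source-node, 8-channel, single-beat experiment."""
    return tv.default_small(seed=7)


@pytest.fixture(scope="session")
def chain_laplacian():
    """1-D cable diffusion operator factory (tridiagonal, zero row sums)."""

    def make(n: int, D: float, h: float = 1.0) -> np.ndarray:
        lap = np.zeros((n, n))
        w = D / h**2
        for i in range(n - 1):
            lap[i, i + 1] = w
            lap[i + 1, i] = w
        np.fill_diagonal(lap, -lap.sum(axis=1))
        return lap

    return make
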