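import numpy as np
import pytest

import clusterselect as cs


@pytest.fixture(scope="session")
def kb():
    return cs.load_kb()


@pytest.fixture(scope="session")
def blobs3():
    """Three well-separated isotropic Gaussian blobs, 20 points each."""
    spec = cs.ClusterSpec(
        sizes=[20, 20, 20],
        means=[[0.0, 0.0], [15.0, 0.0], [0.0, 15.0]],
        covariances=[1.0, 1.0, 1.0],
        seed=4,
    )
    return cs.make_clusters(spec)


@pytest.fixture(scope="session")
def gaussian_spectrum():
    """A single-peak reference spectrum on a 200-point wavenumber grid."""
    grid = np.linspace(1000.0, 2000.0, 200)
    ref = np.exp(-0.5 * ((grid - 1500.0) / 50.0) ** 2)
    return grid, ref
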