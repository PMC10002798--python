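import numpy as np
import pytest

from slacspect import phantom as ph
from slacspect.forward_model import AcquisitionGeometry


@pytest.fixture(scope="session")
def default_phantom():
    """One default-grid phantom shared across tests (read-only)."""
    return ph.generate_phantom(3)


@pytest.fixture(scope="session")
def small_geometry():
    return AcquisitionGeometry(n_angles=12, n_bins=(16, 16))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
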