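import numpy as np
import pytest

from tissuefp import synthgen as sg
from tissuefp.nn import build_tiny_cnn


@pytest.fixture(scope="session")
def small_cohort():
    """4 patients x 2 cores at 512 px: enough for patch/half geometry."""
    return sg.make_cohort(4, cores_per_patient=2, core_px=512, seed=11)


@pytest.fixture(scope="session")
def tiny_model():
    """Untrained tiny backbone over 8 identities."""
    return build_tiny_cnn(n_identities=8, fingerprint_dim=32, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
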