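import numpy as np
import pytest

from flexlink.ensemble import generate_conformers
from flexlink.synthetic import make_two_domain_model


@pytest.fixture(scope="session")
def topology():
    """Helix(15) + linker(20) + globule(60) bead model, 95 residues."""
    return make_two_domain_model(15, 20, 60, seed=0)


@pytest.fixture(scope="session")
def pool(topology):
    """Small conformer pool shared by ensemble tests."""
    return generate_conformers(topology, 30, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
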