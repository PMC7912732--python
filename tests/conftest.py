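import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emip.synthetic import make_toy_system
from emip.topology import MoleculeTopology, SiteParams

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_system():
    return make_toy_system()


@pytest.fixture(scope="session")
def toy_topologies(toy_system):
    return {t.name: t for t in toy_system}


def single_site(name: str, role: str, sigma: float = 3.0,
                epsilon: float = 0.1, charge: float = 0.0
                ) -> MoleculeTopology:
    """One-site rigid molecule used across the MC tests."""
    return MoleculeTopology(
        name, role,
        [SiteParams("X", "C", sigma, epsilon, charge, [0.0, 0.0, 0.0])],
        net_charge=charge)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
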