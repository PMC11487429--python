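import numpy as np
import pytest

from panelpet.coincidence import flat_panel_policy
from panelpet.geometry import CrystalSpec, build_flat_panel, build_reference_ring


@pytest.fixture(scope="session")
def cs3_geometry():
    return build_flat_panel(CrystalSpec(cross_section=3.0, length=10.0, pitch=3.0))


@pytest.fixture(scope="session")
def ring_geometry():
    return build_reference_ring()


@pytest.fixture(scope="session")
def cs3_policy():
    return flat_panel_policy(ctr_ps=75.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
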