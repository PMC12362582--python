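import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_conformer(rng):
    """A generic 12-atom cluster with polar atoms and hydrogens."""
    from protacprofiler.conformers import Conformer

    elements = ["C", "O", "N", "C", "H", "O", "C", "N", "H", "C", "S", "C"]
    coords = rng.normal(scale=2.5, size=(len(elements), 3))
    return Conformer(elements=elements, coords=coords)
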