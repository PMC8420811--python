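import numpy as np
import pytest

from gsttc.scenarios import collision_course_family


@pytest.fixture(scope="session")
def family():
    """The five head-on 2 s baseball flights (15-50 m launch depth)."""
    return collision_course_family()


@pytest.fixture(scope="session")
def family_runs(family):
    """(scenario, trajectory, observer, stream) for each family member."""
    return [(sc, *sc.run()) for sc in family]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
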