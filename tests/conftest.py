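import pytest
from hypothesis import HealthCheck, settings

import camnoise as cn

settings.register_profile(
    "camnoise",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("camnoise")


@pytest.fixture(scope="session")
def cam():
    return cn.buffer_from_table("CaM")


@pytest.fixture(scope="session")
def cam_small(cam):
    """Calcium-calmodulin microdomain, V = 0.125 fl, 100 nM free calcium."""
    return cn.make_system(cam, 0.125, 0.1)


@pytest.fixture(scope="session")
def cam_1fl(cam):
    """Calcium-calmodulin system in a 1 fl voxel."""
    return cn.make_system(cam, 1.0, 0.1)


@pytest.fixture(scope="session")
def tiny_system():
    """Single synthetic buffer with ~17 total calcium ions: small enough for
    exact master-equation enumeration."""
    return cn.make_system(cn.BufferSpec("tiny", 5.0, 1.0, 1.0), 0.05, 0.1)
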