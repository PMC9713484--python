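import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from shootphys.biochem import EnvironmentState
from shootphys.params import LeafParams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def c4_params():
    return LeafParams(pathway="C4")


@pytest.fixture(scope="session")
def c3_params():
    return LeafParams(pathway="C3")


@pytest.fixture
def make_env():
    def _make(**kw):
        defaults = dict(T_a=298.15, P=101325.0, I_s=500.0, VPD=1.5, v=1.5)
        defaults.update(kw)
        return EnvironmentState(**defaults)
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


def random_environment(rng):
    """A physically plausible daytime environment draw."""
    return EnvironmentState(
        T_a=float(rng.uniform(283.0, 313.0)),
        I_s=float(rng.uniform(0.0, 1000.0)),
        VPD=float(rng.uniform(0.2, 3.0)),
        v=float(rng.uniform(0.3, 5.0)),
    )
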