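import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from culturesim.environment import EnvironmentConfig, generate_environment
from culturesim.rng import StreamRNG


@pytest.fixture
def tiny_env_config():
    """2 patch types x 5 types, 4 patches of 10 items, small world."""
    return EnvironmentConfig(
        R=10, n_patch_types=2, types_per_patch_type=5, types_per_patch=3,
        n_patches=4, items_per_patch=10, world_side=100.0)


@pytest.fixture
def tiny_env(tiny_env_config):
    return generate_environment(tiny_env_config, np.random.default_rng(7))


@pytest.fixture
def srng():
    return StreamRNG(123)


class FakePop:
    """Minimal stand-in for the engine's population state, for unit tests
    of the behavior functions (synthetic; positions set by each test)."""

    def __init__(self, n, side=1000.0):
        self.side = side
        self.x = [0.0] * n
        self.y = [0.0] * n
        self.heading = [0.0] * n
        self.group_id = [0] * n
        self.groups = {0: list(range(n))}
        self.action = [6] * n          # NOTHING
        self.eat_type = [-1] * n
        self.se_type = [-1] * n
        self.se_time = [0.0] * n
        self.food_target = [-1] * n
        self.aversions = [dict() for _ in range(n)]
        self.mem_a = np.zeros((n, 10))
        self.mem_c = np.zeros((n, 10))
        self.a_env = np.full(n, 0.1)
        self.p_sigma = [5.0] * n
        self.p_epsilon = [0.1] * n
        self.p_gamma = [0.0] * n


@pytest.fixture
def fake_pop():
    return FakePop
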