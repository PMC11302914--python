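import numpy as np
import pytest
from hypothesis import settings

from afprofile import OptConfig, SurrogateBackend, make_fixtures, make_problem

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_problem():
    """Planted surrogate problem at the default study conditions, L=50."""
    return make_problem(L=50, n_rows=200, noise_sigma=0.1, seed=11)


@pytest.fixture(scope="session")
def small_backend(small_problem):
    return SurrogateBackend(small_problem)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    make_fixtures(seed=7, out=out)
    return out


def deterministic_config(**overrides) -> OptConfig:
    base = dict(
        learning_rate=1e-2, max_iters=100, n_recycles=5,
        stochastic=False, master_seed=0, n_clusters=256,
    )
    base.update(overrides)
    return OptConfig(**base)
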