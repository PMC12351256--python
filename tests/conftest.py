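import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ranksynth.benchmark import run_benchmark
from ranksynth.fixtures import FixtureSpec, make_methane_fixture, make_toy_tables

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toys():
    return make_toy_tables()


@pytest.fixture(scope="session")
def methane_table():
    """One shared synthetic methane stand-in at the compiled-database size."""
    return make_methane_fixture(FixtureSpec(n_rows=263, seed=11))


@pytest.fixture(scope="session")
def rank_bench():
    """Rank-method preservation benchmark at study conditions
    (n=5000, 100 iterations)."""
    return run_benchmark("rank", n=5000, iterations=100, seed=101)


@pytest.fixture(scope="session")
def copula_bench():
    """Copula-method benchmark at the same conditions and module defaults."""
    return run_benchmark("copula", n=5000, iterations=100, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
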