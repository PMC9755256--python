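import numpy as np
import pytest

from moexsim import (
    SimulationParams,
    SiteMap,
    build_behaviour_space,
    run_simulation,
)
from moexsim.experiments import derive_seed, mini_world

#: Condition that reliably produces cultural counts around the
#: 38-trait benchmark: full social mediation, high ecological and
#: moderate genetic cross-site variability.
BENCHMARK = dict(S=1.0, alpha_g=0.2, alpha_e=0.8, t_max=6000)


@pytest.fixture(scope="session")
def sites():
    return SiteMap.default()


@pytest.fixture(scope="session")
def space():
    return build_behaviour_space()


@pytest.fixture(scope="session")
def mini():
    """(sites, space) of the fast 2-site, 8-behaviour world."""
    return mini_world()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark_runs():
    """Twenty full-length runs at the benchmark condition, shared by
    the distribution-level checks."""
    return [
        run_simulation(SimulationParams(**BENCHMARK, seed=derive_seed(0, 2, i)))
        for i in range(20)
    ]
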