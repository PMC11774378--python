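import numpy as np
import pytest

from qfasa import (
    PreyLibrary,
    SignatureMatrix,
    SimulationSpec,
    simulate_cc,
    simulate_predators,
    simulate_prey_library,
)


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(
        G=4, K=10, n_per_group=6, n_predators=8,
        noise_spread=0.0, cc_spread=0.2, seed=11,
    )


@pytest.fixture(scope="session")
def small_library(small_spec):
    return simulate_prey_library(small_spec)


@pytest.fixture(scope="session")
def small_cc(small_spec):
    return simulate_cc(small_spec)


@pytest.fixture(scope="session")
def small_predators(small_library, small_cc, small_spec):
    return simulate_predators(small_library, small_cc, small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, ids=None, fa_names=None, completed=False):
    values = np.asarray(values, float)
    n, k = values.shape
    return SignatureMatrix(
        ids or [f"s{i}" for i in range(n)],
        fa_names or [f"fa_{j}" for j in range(k)],
        values,
        completed=completed,
    )


def make_library(values, labels, **kw):
    return PreyLibrary(make_matrix(values, **kw), labels)
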