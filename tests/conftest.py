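import numpy as np
import pytest

from stdpnet import (ConnectivityState, effective_connectivity, make_alpha_kernel,
                     make_stdp, stationary_rates)


@pytest.fixture(scope="session")
def kernel():
    """Default synaptic current: tau1 = 5 ms, tau2 = 1 s, zero latency."""
    return make_alpha_kernel(5e-3, 1.0, 0.0)


@pytest.fixture(scope="session")
def antisym():
    return make_stdp("antisymmetric")


@pytest.fixture(scope="session")
def mexhat():
    return make_stdp("mexican_hat")


@pytest.fixture(scope="session")
def asym():
    return make_stdp("asymmetric")


@pytest.fixture(scope="session")
def stdp_families(antisym, mexhat, asym):
    return {"antisymmetric": antisym, "mexican_hat": mexhat, "asymmetric": asym}


def random_stable_state(n=5, radius=0.5, seed=0, w_max=1.0):
    """Random non-negative connectivity rescaled to the given spectral radius."""
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.0, 1.0, (n, n))
    np.fill_diagonal(W, 0.0)
    W *= radius / np.max(np.abs(np.linalg.eigvals(W)))
    return ConnectivityState(W, w_max)


@pytest.fixture
def stable5():
    """Random stable 5-neuron network (spectral radius 0.5) with its rates."""
    state = random_stable_state(5, 0.5, seed=3)
    rates = stationary_rates(state.W_ex, 15.0)
    return state, rates
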