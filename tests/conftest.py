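import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from recurnet import make_fixture  # noqa: E402


@pytest.fixture
def tiny_separable():
    return make_fixture("tiny_separable")


@pytest.fixture
def tiny_tied():
    return make_fixture("tiny_tied")


@pytest.fixture
def tiny_disconnected():
    return make_fixture("tiny_disconnected")


def random_connected_weights(rng, n, extra_edges=None):
    """Random symmetric weight matrix guaranteed connected.

    A random spanning chain plus extra random edges, uniform weights.
    """
    if extra_edges is None:
        extra_edges = 2 * n
    W = np.zeros((n, n))
    perm = rng.permutation(n)
    for a, b in zip(perm[:-1], perm[1:]):
        W[a, b] = W[b, a] = rng.uniform(0.1, 1.0)
    for _ in range(extra_edges):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            W[a, b] = W[b, a] = rng.uniform(0.1, 1.0)
    return W


def clamped_propagation_oracle(W, f_l, tol=1e-13, max_iter=500_000):
    """Fixed-point label propagation: f <- D^-1 W f with labeled re-clamped.

    Independent iterative oracle for the direct harmonic solve.
    """
    n = W.shape[0]
    l = len(f_l)
    deg = W.sum(axis=1)
    f = np.full(n, f_l.mean())
    f[:l] = f_l
    active = deg[l:] > 0
    for _ in range(max_iter):
        new_u = f[l:].copy()
        upd = (W[l:] @ f)[active] / deg[l:][active]
        delta = np.abs(upd - new_u[active]).max() if active.any() else 0.0
        new_u[active] = upd
        f[l:] = new_u
        if delta < tol:
            break
    return f[l:]


@pytest.fixture
def connected_graph_factory():
    return random_connected_weights


@pytest.fixture
def propagation_oracle():
    return clamped_propagation_oracle
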