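import numpy as np
import pytest

from stdpmem import GenSpec, fixture, random_network


@pytest.fixture
def f4():
    return fixture("F4")


@pytest.fixture
def s1():
    return fixture("S1")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_random_dense(rng, max_side=8, rho=0.5):
    M = int(rng.integers(1, max_side + 1))
    N = int(rng.integers(1, max_side + 1))
    return random_network(GenSpec(M, N, rho, seed=int(rng.integers(2 ** 31))))


def forced_train(rng, t_refr, n_steps, p=0.25):
    """Random spike steps with the minimum inter-spike spacing t_refr + 1."""
    out, last = [], -(10 ** 9)
    for s in range(n_steps):
        if s - last > t_refr and rng.random() < p:
            out.append(s)
            last = s
    return tuple(out)
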