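import numpy as np
import pytest

from targetcontrol import DirectedNetwork, RandomNetSpec, RankedTargetSet, make_random_network


@pytest.fixture
def path_net():
    """Directed path v1 -> v2 -> v3 -> v4 -> v5."""
    return DirectedNetwork.from_edges(
        [("v1", "v2"), ("v2", "v3"), ("v3", "v4"), ("v4", "v5")]
    )


@pytest.fixture
def star_net():
    """Star a -> x, a -> y (identical walk-count rows for x and y)."""
    return DirectedNetwork.from_edges([("a", "x"), ("a", "y")])


@pytest.fixture
def cycle3():
    """Directed 3-cycle a -> b -> c -> a."""
    return DirectedNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "a")])


def random_instance(rng, n_lo=6, n_hi=12, d_lo=0.05, d_hi=0.30, s_lo=3, s_hi=5):
    """One random network + driver + ranked targets, for oracle-scale checks."""
    n = int(rng.integers(n_lo, n_hi + 1))
    density = float(rng.uniform(d_lo, d_hi))
    lo_feasible = 1.0 / (n * (n - 1)) + 1e-9
    density = max(density, lo_feasible)
    net = make_random_network(
        RandomNetSpec(n=n, density=density), seed=int(rng.integers(2**31))
    )
    nodes = list(net.nodes)
    s = int(rng.integers(s_lo, min(s_hi, n - 1) + 1))
    picks = rng.choice(len(nodes), size=s + 1, replace=False)
    driver = nodes[int(picks[0])]
    ranked = RankedTargetSet([nodes[int(i)] for i in picks[1:]])
    return net, driver, ranked


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
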