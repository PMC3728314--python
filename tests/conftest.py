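import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from sisqsd import ContactNetwork, complete_network, random_strongly_connected_network


@pytest.fixture
def two_node_symmetric():
    """2-node network with beta=1 both ways, g=1: the closed-form case
    (alpha = 2 - sqrt(2), marginal prevalence = invasion = sqrt(2)/2)."""
    return complete_network(2, 1.0)


@pytest.fixture
def two_node_asymmetric():
    w = np.array([[0.0, 2.0], [1.0, 0.0]])
    return ContactNetwork(weights=sp.csr_array(w), recovery=np.ones(2))


def random_net(n, seed, extra=0.3, weights=(0.1, 1.0), recovery=1.0):
    return random_strongly_connected_network(
        n, extra, weight_sampler=weights, seed=seed, recovery=recovery
    )


def symmetrise(net: ContactNetwork) -> ContactNetwork:
    w = net.dense()
    w = np.maximum(w, w.T)
    return ContactNetwork(weights=sp.csr_array(w), recovery=net.recovery.copy())


def brute_force_sccs(adj: np.ndarray) -> list[frozenset]:
    """Reachability-closure SCC oracle, O(n^3); for n <= 8 only."""
    n = adj.shape[0]
    reach = (adj > 0) | np.eye(n, dtype=bool)
    for _ in range(n):
        reach = reach | (reach @ reach)
    comps = set()
    for i in range(n):
        comps.add(frozenset(j for j in range(n) if reach[i, j] and reach[j, i]))
    return sorted(comps, key=lambda c: min(c))


def nonempty_subsets(n):
    nodes = range(n)
    for k in range(1, n + 1):
        yield from (frozenset(c) for c in itertools.combinations(nodes, k))
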