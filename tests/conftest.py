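import numpy as np
import pytest

from moanet import (
    Edge,
    SignedDirectedNetwork,
    Stimulus,
    generate_network,
    plant_instance,
)


@pytest.fixture(scope="session")
def chain():
    """S -> A -> B chain with unit weights, S clamped +1."""
    net = SignedDirectedNetwork(
        [Edge("S", "A", 1, 1.0), Edge("A", "B", 1, 1.0)]
    )
    return net, Stimulus({"S": 1})


@pytest.fixture(scope="session")
def toy_instance():
    """Small planted instance used by fast unit tests."""
    net = generate_network(n_nodes=120, attach_m=2, p_inhibition=0.3, seed=11)
    return plant_instance(
        net, n_targets=2, n_eff_ind=8, n_eff_adv=8,
        n_extra_restrictions=10, restriction_noise=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def default_instance():
    """The default-scale planted instance (matches the pipeline defaults)."""
    net = generate_network(n_nodes=300, attach_m=2, p_inhibition=0.3, seed=7)
    return plant_instance(net, seed=7)


def random_network(rng: np.random.Generator, n_nodes: int = 12, n_edges: int = 20):
    """Random signed directed network for round-trip/property tests."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    pairs = set()
    while len(pairs) < n_edges:
        i, j = rng.integers(n_nodes, size=2)
        if i != j:
            pairs.add((nodes[i], nodes[j]))
    edges = [
        Edge(s, t, int(rng.choice([-1, 1])), float(np.round(rng.uniform(-1, 1), 6)))
        for s, t in sorted(pairs)
    ]
    return SignedDirectedNetwork(edges)
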