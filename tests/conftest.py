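import numpy as np
import pytest

from braingc.synthetic import CouplingGraph, MVARSpec


def two_node_spec(weight: float, seed: int, self_coef: float = 0.5) -> MVARSpec:
    """A minimal VAR(1) pair: node 0 drives node 1 with the given weight."""
    edges = ((0, 1),) if weight != 0 else ()
    weights = (weight,) if weight != 0 else ()
    graph = CouplingGraph(2, edges, weights, ("ch1", "ch2"))
    return MVARSpec(
        coupling=graph,
        self_dynamics=((self_coef,), (self_coef,)),
        noise_sd=(1.0, 1.0),
        sample_rate=1000.0,
        seed=seed,
        observation_noise_sd=0.0,
    )


@pytest.fixture
def random_digraphs():
    """50 random directed graphs on <= 15 nodes with mixed densities."""
    rng = np.random.default_rng(20240)
    graphs = []
    for _ in range(50):
        n = int(rng.integers(3, 16))
        density = rng.uniform(0.05, 0.6)
        adj = rng.random((n, n)) < density
        np.fill_diagonal(adj, False)
        graphs.append(adj)
    return graphs
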