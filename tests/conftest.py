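import io

import numpy as np
import pytest

import trnet


FIG_EXAMPLE_EDGES = "1\t2\t0.1\n2\t3\t0.3\n2\t4\t0.8\n1\t4\t0.5\n3\t4\t0.2\n"


@pytest.fixture
def chain_with_shortcuts():
    """4-node chain 1->2->3->4 plus two less-certain shortcuts (1,4), (2,4).

    The minimax uncertainty of the indirect route 1->2->3->4 is 0.3, so
    the weighted reduction must drop both shortcuts.
    """
    return trnet.read_graph(io.StringIO(FIG_EXAMPLE_EDGES))


@pytest.fixture
def protected_diamond():
    """Graph where t_low = 0.5 protects (b,c) and hides the best path.

    With the protection active the best visible alternative for (d,c)
    is d->b->c at 0.5 rather than d->b->a->c at 0.3.
    """
    return trnet.WeightedDigraph.from_edges(
        [("d", "b", 0.1), ("b", "a", 0.2), ("a", "c", 0.3),
         ("b", "c", 0.5), ("d", "c", 0.6)],
        nodes=["a", "b", "c", "d"],
    )


def random_weighted(n, density, seed, model="erdos_renyi"):
    topo = trnet.random_digraph(n, model=model, density=density, seed=seed)
    return trnet.assign_weights(topo, "uniform", seed=seed + 10_000)


def edge_set(g):
    if isinstance(g, trnet.WeightedDigraph):
        return {(u, v) for u, v, _ in g.edges()}
    return set(g.edges())
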