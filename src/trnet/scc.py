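"""Strongly connected component condensation and re-expansion.

Transitive reduction of a cyclic unweighted graph is not unique and may
even require edges absent from the input.  The classical workaround is
to contract each strongly connected component (SCC) to a single node,
reduce the resulting acyclic component graph, and then re-expand the
components exactly as they appeared in the original graph.  This module
provides the contraction (:func:`condense`) and the re-expansion
(:func:`expand`); the acyclic reduction itself lives in
:mod:`trnet.reduction`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TextIO

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .graph_model import UnweightedDigraph

__all__ = ["Condensation", "condense", "expand"]


@dataclass
class Condensation:
    """SCC partition of a digraph together with its component DAG.

    ``component_of[i]`` maps node index ``i`` to its component index;
    ``components[c]`` is the set of node indices in component ``c``;
    ``dag`` is the acyclic graph over components whose edge (C1, C2)
    exists iff some original edge runs from a node of C1 to a node of C2.
    Components are numbered by first-encountered member in node-index
    order, so the numbering is deterministic.
    """

    component_of: np.ndarray
    components: list[set[int]]
    dag: UnweightedDigraph

    @property
    def n_components(self) -> int:
        return len(self.components)

    def dump(self, stream: TextIO) -> None:
        """Write the node -> component map as two-column TSV."""
        for i, c in enumerate(self.component_of):
            stream.write(f"{i}\t{int(c)}\n")


def condense(g: UnweightedDigraph) -> Condensation:
    """Contract every strongly connected component to a single node."""
    n = g.n
    if n == 0:
        return Condensation(
            np.zeros(0, dtype=int), [], UnweightedDigraph([], np.zeros((0, 0), bool))
        )
    adj = csr_matrix(g.adjacency)
    _, raw_labels = connected_components(adj, directed=True, connection="strong")
    # renumber so that component ids follow first appearance in index order
    remap: dict[int, int] = {}
    component_of = np.empty(n, dtype=int)
    for i, lab in enumerate(raw_labels):
        if lab not in remap:
            remap[int(lab)] = len(remap)
        component_of[i] = remap[int(lab)]
    ncomp = len(remap)
    components: list[set[int]] = [set() for _ in range(ncomp)]
    for i, c in enumerate(component_of):
        components[c].add(i)

    dag_adj = np.zeros((ncomp, ncomp), dtype=bool)
    src, dst = np.nonzero(g.adjacency)
    cs, cd = component_of[src], component_of[dst]
    off = cs != cd
    dag_adj[cs[off], cd[off]] = True
    dag = UnweightedDigraph([f"C{c}" for c in range(ncomp)], dag_adj)
    return Condensation(component_of, components, dag)


def expand(
    reduced_dag: UnweightedDigraph,
    c: Condensation,
    original: UnweightedDigraph,
    policy: str = "all",
) -> UnweightedDigraph:
    """Re-expand a reduced component DAG back onto the original nodes.

    The output keeps (i) every original edge internal to a component,
    untouched, and (ii) for each surviving DAG edge (C1, C2), the
    original edges from C1 to C2 — all of them under ``policy="all"``,
    or only the (index-order) first under ``policy="first"``.
    """
    if reduced_dag.n != c.n_components:
        raise ValueError(
            f"reduced dag has {reduced_dag.n} nodes but condensation has "
            f"{c.n_components} components"
        )
    if policy not in ("all", "first"):
        raise ValueError(f"unknown expand policy {policy!r}")
    out = np.zeros_like(original.adjacency)
    src, dst = np.nonzero(original.adjacency)
    cs, cd = c.component_of[src], c.component_of[dst]
    intra = cs == cd
    out[src[intra], dst[intra]] = True
    if policy == "all":
        keep = (~intra) & reduced_dag.adjacency[cs, cd]
        out[src[keep], dst[keep]] = True
    else:
        chosen: set[tuple[int, int]] = set()
        for i, j, ci, cj in zip(src, dst, cs, cd):  # (i, j) in index order
            if ci != cj and reduced_dag.adjacency[ci, cj] and (ci, cj) not in chosen:
                out[i, j] = True
                chosen.add((int(ci), int(cj)))
    return UnweightedDigraph(list(original.node_labels), out)
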