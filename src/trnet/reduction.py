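"""Transitive reduction of directed graphs, unweighted and weighted.

The unweighted reduction of an acyclic graph deletes every edge (i, j)
for which an indirect path i -> ... -> j of length at least two exists;
the result is the unique smallest graph with the same transitive closure.
Cyclic inputs are handled by condensing strongly connected components
first (:func:`tr_unweighted`).

The weighted reduction treats edge weights as interaction uncertainties
(smaller = more certain) and applies the weakest-link principle: the
uncertainty of a path is the maximum weight along it,

    W(P) = max_{e in P} w(e),

and the minimal transitive interaction uncertainty between i and j is
the strongest weakest link over all paths,

    h(i, j) = min_{P in Paths(i, j)} W(P).

An edge survives the weighted reduction iff its own weight equals
h(i, j) — i.e. no strictly more certain indirect route exists.  Because
W never decreases when a cycle is inserted into a path, cycles are
harmless and need no special treatment.  Two optional thresholds refine
the rule: edges with w <= t_low are kept unconditionally, edges with
w >= t_up removed unconditionally.

All-pairs h is computed by a Floyd–Warshall sweep in (min, max) algebra
(:func:`minimax_uncertainty`).  The sweep keeps a single value matrix
plus a boolean deletion-marker table: when a strictly better indirect
route overwrites an edge's entry, the marker records that the edge is
doomed while its improved magnitude stays available to later
iterations.  (A sign bit on the value would serve the same purpose but
cannot encode deletion for a weight of exactly 0.)  For a fixed outer
pivot order the result is independent of the inner iteration order, and
the final edge set is independent of the pivot order as well.

:func:`brute_force_h` enumerates simple paths (and simple cycles for the
diagonal) and exists purely as an independent oracle for small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TextIO

import networkx as nx
import numpy as np

from .graph_model import (
    DISABLED,
    NO_EDGE,
    Thresholds,
    UnweightedDigraph,
    WeightedDigraph,
)
from .scc import condense, expand

__all__ = [
    "UncertaintyMatrix",
    "CyclicGraphError",
    "path_uncertainty",
    "transitive_closure",
    "tr_unweighted_acyclic",
    "tr_unweighted",
    "minimax_uncertainty",
    "tr_weighted",
    "brute_force_h",
    "apply_upper_threshold",
]


class CyclicGraphError(ValueError):
    """Raised when an acyclic-only routine receives a cyclic graph."""


@dataclass
class UncertaintyMatrix:
    """All-pairs path uncertainties with deletion markers.

    ``values[i, j]`` holds the best path uncertainty found between i and
    j (``NO_EDGE`` when no path is known); ``deleted[i, j]`` is True
    when the entry for an original edge has been overwritten by a
    strictly better indirect route, i.e. the edge fails the reduction
    criterion.  With thresholds disabled the final values equal the
    minimal transitive interaction uncertainty h(i, j) exactly.
    """

    values: np.ndarray
    deleted: np.ndarray

    def dump(self, stream: TextIO, labels: Sequence[str]) -> None:
        """Write values as labeled CSV (``inf`` = unreachable) followed by
        a 0/1 marker matrix."""
        stream.write("," + ",".join(labels) + "\n")
        for i, lab in enumerate(labels):
            cells = [
                "inf" if not np.isfinite(v) else repr(float(v)) for v in self.values[i]
            ]
            stream.write(lab + "," + ",".join(cells) + "\n")
        stream.write("#deleted\n")
        for i, lab in enumerate(labels):
            stream.write(lab + "," + ",".join(str(int(d)) for d in self.deleted[i]) + "\n")


def path_uncertainty(g: WeightedDigraph, path: Sequence[str | int]) -> float:
    """Weakest-link uncertainty W(P): the maximum edge weight along ``path``.

    ``path`` is a sequence of node labels (or indices) of length >= 2;
    every consecutive pair must be an edge of ``g``.
    """
    if len(path) < 2:
        raise ValueError("a path needs at least two nodes (one edge)")
    idx = [p if isinstance(p, (int, np.integer)) else g.index(p) for p in path]
    worst = -np.inf
    for a, b in zip(idx, idx[1:]):
        w = g.weights[a, b]
        if not np.isfinite(w):
            raise ValueError(
                f"({g.node_labels[a]}, {g.node_labels[b]}) is not an edge of the graph"
            )
        worst = max(worst, float(w))
    return worst


def transitive_closure(g: UnweightedDigraph) -> UnweightedDigraph:
    """Graph with an edge (i, j) wherever a path of length >= 1 runs i -> j.

    Reflexive pairs appear only when i lies on a cycle.
    """
    reach = g.adjacency.copy()
    for k in range(g.n):
        reach |= np.outer(reach[:, k], reach[k, :])
    return UnweightedDigraph(list(g.node_labels), reach)


def tr_unweighted_acyclic(g: UnweightedDigraph) -> UnweightedDigraph:
    """Transitive reduction of an acyclic graph.

    Deletes exactly the edges (i, j) with an indirect i -> j path of
    length >= 2; the result is the unique minimal subgraph with the same
    transitive closure.  Raises :class:`CyclicGraphError` on cyclic
    input (including self-loops) — use :func:`tr_unweighted` there.
    """
    if np.diagonal(g.adjacency).any():
        raise CyclicGraphError(
            "graph has self-loops; use tr_unweighted for cyclic graphs"
        )
    # Floyd–Warshall sweep marking pairs joined by a path of length >= 2
    b = g.adjacency.astype(np.int8)
    for k in range(g.n):
        via = np.outer(b[:, k] >= 1, b[k, :] >= 1)
        b[via] = 2
    if (np.diagonal(b) >= 1).any():
        raise CyclicGraphError("graph contains a cycle; use tr_unweighted")
    out = g.adjacency & ~(b == 2)
    return UnweightedDigraph(list(g.node_labels), out)


def tr_unweighted(g: UnweightedDigraph, expand_policy: str = "all") -> UnweightedDigraph:
    """Transitive reduction of a possibly cyclic unweighted graph.

    Strongly connected components are contracted, the acyclic component
    DAG is reduced, and components are re-expanded as they were in the
    input.  Edges inside a component are never removed.  On acyclic
    input this coincides with :func:`tr_unweighted_acyclic`.
    """
    c = condense(g)
    reduced = tr_unweighted_acyclic(c.dag)
    return expand(reduced, c, g, policy=expand_policy)


def minimax_uncertainty(
    g: WeightedDigraph,
    thresholds: Thresholds = DISABLED,
    node_order: Sequence[int] | None = None,
) -> UncertaintyMatrix:
    """Floyd–Warshall sweep computing all-pairs minimax path uncertainty.

    For each pivot k (in ``node_order``, default index order), every
    pair (i, j) is offered the route i -> k -> j with uncertainty
    ``viaK = max(|B[i,k]|, |B[k,j]|)``; the entry is updated — and the
    deletion marker set — whenever viaK is strictly smaller than the
    current magnitude.  Edges protected by the lower threshold
    (w <= t_low) are never updated, so intermediate values are
    pivot-order-dependent when protection is active; with t_low disabled
    the final values equal h(i, j) for every pair joined by a path,
    whatever the order.
    """
    n = g.n
    if node_order is None:
        order: Sequence[int] = range(n)
    else:
        order = list(node_order)
        if sorted(order) != list(range(n)):
            raise ValueError("node_order must be a permutation of 0..n-1")
    b = g.weights.copy()
    protected = g.edge_mask & (g.weights <= thresholds.low)
    deleted = np.zeros((n, n), dtype=bool)
    for k in order:
        via = np.maximum.outer(b[:, k], b[k, :])
        better = (via < b) & ~protected
        b[better] = via[better]
        deleted |= better
    return UncertaintyMatrix(b, deleted)


def tr_weighted(
    g: WeightedDigraph, thresholds: Thresholds = DISABLED
) -> WeightedDigraph:
    """Weighted transitive reduction.

    Kept edges retain their original weights.  An edge is kept iff
    w <= t_low, or w < t_up and no strictly more certain indirect route
    exists (w(e) = h(e)); ties between the direct edge and its best
    alternative keep the edge.  Cycles are allowed; self-loop entries
    are treated like any other pair.
    """
    um = minimax_uncertainty(g, thresholds)
    keep = g.edge_mask & ~um.deleted & (g.weights < thresholds.up)
    w = np.where(keep, g.weights, NO_EDGE)
    return WeightedDigraph(list(g.node_labels), w)


def apply_upper_threshold(g: WeightedDigraph, t_up: float) -> WeightedDigraph:
    """Drop exactly the edges with weight >= ``t_up``.

    Pure filtering, independent of the reduction: it commutes with
    :func:`tr_weighted` used with the same upper threshold.
    """
    w = np.where(g.weights >= t_up, NO_EDGE, g.weights)
    return WeightedDigraph(list(g.node_labels), w)


_BRUTE_FORCE_LIMIT = 12


def brute_force_h(g: WeightedDigraph) -> UncertaintyMatrix:
    """Minimax uncertainties by exhaustive simple-path enumeration.

    Independent oracle for :func:`minimax_uncertainty`: h(i, j) is the
    minimum of W(P) over all simple paths i -> j (simple cycles through
    i when i = j, self-loops included); NO_EDGE where no path exists.
    Deletion markers reproduce the sweep's semantics: an edge whose
    weight exceeds h, or a non-edge pair joined by any path.  Guarded to
    n <= 12 nodes.
    """
    n = g.n
    if n > _BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"brute_force_h enumerates simple paths; n={n} exceeds the "
            f"guard of {_BRUTE_FORCE_LIMIT}"
        )
    gx = nx.DiGraph()
    gx.add_nodes_from(range(n))
    src, dst = np.nonzero(g.edge_mask)
    for i, j in zip(src, dst):
        gx.add_edge(int(i), int(j), w=float(g.weights[i, j]))
    h = np.full((n, n), NO_EDGE)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for p in nx.all_simple_paths(gx, i, j):
                wmax = max(gx[a][b]["w"] for a, b in zip(p, p[1:]))
                h[i, j] = min(h[i, j], wmax)
    for cyc in nx.simple_cycles(gx):
        wmax = max(
            gx[a][b]["w"] for a, b in zip(cyc, cyc[1:] + cyc[:1])
        )
        for i in cyc:
            h[i, i] = min(h[i, i], wmax)
    deleted = (g.edge_mask & (h < g.weights)) | (~g.edge_mask & np.isfinite(h))
    return UncertaintyMatrix(h, deleted)
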