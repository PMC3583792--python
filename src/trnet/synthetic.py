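"""Synthetic perturbation graphs and edge-ranking evaluation.

Perturbation experiments (gene knockouts/knockdowns) observe effects
along every causal route, so the network read directly off the data
approximates the *transitive closure* of the true regulatory network:
each indirect influence shows up as a spurious direct edge, typically
with slightly higher uncertainty than the best true route that explains
it.  The generators here emulate exactly that: a seeded random true
network (DAG, Erdős–Rényi or directed scale-free), p-value-like edge
uncertainties, and a perturbation graph built as the closure of the
true network in which every added indirect edge carries the minimax
uncertainty of its best explaining path plus a small offset ``eps``,
optionally contaminated with spurious noise edges.  Because every added
edge is strictly less certain than its best indirect route, the
weighted transitive reduction provably recovers the noise-free true
network — which turns a qualitative reconstruction claim into a
deterministic test.

Evaluation follows the DREAM-challenge recipe: the candidate edges are
ranked in three blocks — accepted by the reduction, accepted by the
first filtering step but cut by the reduction, never accepted — each
block sorted by uncertainty, and AUROC/AUPR are computed for that
ranking against a gold-standard network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import TextIO

import networkx as nx
import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph_model import NO_EDGE, UnweightedDigraph, WeightedDigraph
from .reduction import minimax_uncertainty

__all__ = [
    "EvalReport",
    "RankedEdgeClasses",
    "random_digraph",
    "assign_weights",
    "make_perturbation_graph",
    "confusion_counts",
    "ranked_edges",
    "auroc_aupr",
    "evaluate",
]


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and ranking scores over ordered node pairs
    (diagonal excluded); ``tp + tn + fp + fn = n (n - 1)``."""

    tp: int
    tn: int
    fp: int
    fn: int
    auroc: float
    aupr: float

    def to_json(self, stream: TextIO | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if stream is not None:
            stream.write(text + "\n")
        return text


@dataclass
class RankedEdgeClasses:
    """Three-block edge ranking used for DREAM-style scoring.

    ``class1``: edges surviving the reduction; ``class2``: edges present
    in the perturbation graph but cut by the reduction; ``class3``: node
    pairs never proposed as edges.  Blocks 1–2 are sorted by uncertainty
    (ascending by default: most certain first), block 3 is in index
    order; their concatenation is the evaluation ranking and partitions
    the off-diagonal pairs.
    """

    class1: list[tuple[int, int]]
    class2: list[tuple[int, int]]
    class3: list[tuple[int, int]]

    def ranking(self) -> list[tuple[int, int]]:
        return self.class1 + self.class2 + self.class3

    def write(self, stream: TextIO, labels: list[str]) -> None:
        for name, block in (("1", self.class1), ("2", self.class2), ("3", self.class3)):
            stream.write(f"#class {name}\n")
            for i, j in block:
                stream.write(f"{labels[i]}\t{labels[j]}\n")


def random_digraph(
    n: int,
    model: str = "erdos_renyi",
    density: float = 0.1,
    seed: int | None = None,
) -> UnweightedDigraph:
    """Seeded random directed graph.

    ``model`` is one of:

    * ``"dag"`` — each pair (i, j) with i < j is an edge with
      probability ``density``; edges only run from lower to higher
      index, so the result is acyclic by construction.
    * ``"erdos_renyi"`` — each ordered off-diagonal pair independently
      with probability ``density``.
    * ``"scale_free"`` — directed preferential attachment (heavy-tailed
      in- and out-degrees); ``density`` is ignored for this model and
      the graph is simplified to single edges without self-loops.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must lie in [0, 1], got {density}")
    labels = [f"G{i + 1}" for i in range(n)]
    rng = np.random.default_rng(seed)
    if model == "dag":
        adj = np.triu(rng.random((n, n)) < density, k=1)
    elif model == "erdos_renyi":
        adj = rng.random((n, n)) < density
        np.fill_diagonal(adj, False)
    elif model == "scale_free":
        adj = np.zeros((n, n), dtype=bool)
        if n > 1:
            gx = nx.scale_free_graph(n, seed=int(rng.integers(2**31)))
            for u, v in gx.edges():
                if u != v:
                    adj[u, v] = True
    else:
        raise ValueError(f"unknown model {model!r}")
    return UnweightedDigraph(labels, adj)


def assign_weights(
    g: UnweightedDigraph,
    distribution: str = "uniform",
    seed: int | None = None,
    value: float = 0.5,
) -> WeightedDigraph:
    """Attach interaction uncertainties to every edge.

    ``distribution="uniform"`` draws each weight independently from the
    open unit interval, mimicking p-values of true interactions;
    ``"fixed"`` assigns the constant ``value``.  Non-edges get the
    no-edge sentinel.  Identical seeds yield identical weight tables.
    """
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        draws = rng.random((g.n, g.n))
        # exclude exact 0: a weight of 0 is maximally certain, keep it open
        draws = np.nextafter(draws, 1.0)
    elif distribution == "fixed":
        draws = np.full((g.n, g.n), float(value))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    w = np.where(g.adjacency, draws, NO_EDGE)
    return WeightedDigraph(list(g.node_labels), w)


def make_perturbation_graph(
    true_g: WeightedDigraph,
    eps: float = 0.05,
    spurious_rate: float = 0.0,
    seed: int | None = None,
) -> WeightedDigraph:
    """Emulate the network read directly off perturbation experiments.

    The output is the transitive closure of ``true_g``: every true edge
    is kept at its original weight, and every reachable non-adjacent
    ordered pair (i, j), i != j, gains an edge weighted
    ``h(i, j) + eps`` — slightly *less* certain than the best indirect
    path that explains it (capped below the no-edge sentinel).  A
    fraction ``spurious_rate`` of the remaining unreachable pairs is
    additionally flipped to noise edges with uniform random weights.

    When ``true_g`` is already transitively reduced (thresholds
    disabled) and ``spurious_rate`` is 0, applying the weighted
    reduction to the result returns ``true_g`` exactly.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if not 0.0 <= spurious_rate <= 1.0:
        raise ValueError("spurious_rate must lie in [0, 1]")
    n = true_g.n
    h = minimax_uncertainty(true_g).values
    w = true_g.weights.copy()
    reachable = np.isfinite(h)
    addable = reachable & ~true_g.edge_mask
    np.fill_diagonal(addable, False)
    cap = np.finfo(float).max
    w[addable] = np.minimum(h[addable] + eps, cap)

    if spurious_rate > 0:
        rng = np.random.default_rng(seed)
        free = ~np.isfinite(w)
        np.fill_diagonal(free, False)
        flip = free & (rng.random((n, n)) < spurious_rate)
        w[flip] = np.nextafter(rng.random((n, n))[flip], 1.0)
    return WeightedDigraph(list(true_g.node_labels), w)


def _offdiag_mask(n: int) -> np.ndarray:
    m = np.ones((n, n), dtype=bool)
    np.fill_diagonal(m, False)
    return m


def confusion_counts(
    predicted: UnweightedDigraph, gold: UnweightedDigraph
) -> tuple[int, int, int, int]:
    """(tp, tn, fp, fn) over ordered off-diagonal node pairs."""
    if predicted.node_labels != gold.node_labels:
        raise ValueError("predicted and gold graphs have different node sets")
    off = _offdiag_mask(predicted.n)
    p, g = predicted.adjacency & off, gold.adjacency & off
    tp = int((p & g).sum())
    fp = int((p & ~g & off).sum())
    fn = int((~p & g & off).sum())
    tn = int((~p & ~g & off).sum())
    return tp, tn, fp, fn


def ranked_edges(
    perturbation_g: WeightedDigraph,
    reduced_g: WeightedDigraph,
    direction: str = "ascending",
) -> RankedEdgeClasses:
    """Three-block DREAM-style ranking of all ordered node pairs.

    The reduced edge set must be a subset of the perturbation edges.
    Blocks 1 and 2 are sorted by weight (``"ascending"``: smallest
    uncertainty first, the default for p-value-like weights;
    ``"descending"`` for correlation-like scores), ties broken by
    (i, j) index; block 3 in index order.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError(f"unknown direction {direction!r}")
    pe, re_ = perturbation_g.edge_mask, reduced_g.edge_mask
    if (re_ & ~pe).any():
        raise ValueError("reduced graph has edges absent from the perturbation graph")
    off = _offdiag_mask(perturbation_g.n)
    sign = 1.0 if direction == "ascending" else -1.0

    def sorted_block(mask: np.ndarray, weights: np.ndarray) -> list[tuple[int, int]]:
        idx = [(int(i), int(j)) for i, j in zip(*np.nonzero(mask & off))]
        return sorted(idx, key=lambda ij: (sign * weights[ij], ij))

    class1 = sorted_block(re_, reduced_g.weights)
    class2 = sorted_block(pe & ~re_, perturbation_g.weights)
    class3 = [(int(i), int(j)) for i, j in zip(*np.nonzero(~pe & off))]
    return RankedEdgeClasses(class1, class2, class3)


def auroc_aupr(
    ranking: RankedEdgeClasses, gold: UnweightedDigraph
) -> tuple[float, float]:
    """Score a full edge ranking against a gold-standard network.

    AUROC by the trapezoidal rule over the ranking; AUPR by step-wise
    precision-recall summation (average precision).  The ranking must
    cover every ordered off-diagonal pair; a gold standard with no
    positive or no negative pairs leaves both areas undefined and
    raises ``ValueError``.
    """
    n = gold.n
    pairs = ranking.ranking()
    if sorted(pairs) != [(i, j) for i in range(n) for j in range(n) if i != j]:
        raise ValueError("ranking does not cover the off-diagonal pairs exactly once")
    y = np.array([bool(gold.adjacency[i, j]) for i, j in pairs])
    if y.all() or not y.any():
        raise ValueError("gold standard needs at least one positive and one negative")
    scores = -np.arange(len(pairs), dtype=float)  # earlier rank = higher score
    return float(roc_auc_score(y, scores)), float(average_precision_score(y, scores))


def evaluate(
    perturbation_g: WeightedDigraph,
    reduced_g: WeightedDigraph,
    gold: UnweightedDigraph,
    direction: str = "ascending",
) -> EvalReport:
    """Confusion counts of the reduced graph plus ranking scores."""
    from .graph_model import as_unweighted

    tp, tn, fp, fn = confusion_counts(as_unweighted(reduced_g), gold)
    ranking = ranked_edges(perturbation_g, reduced_g, direction)
    auroc, aupr = auroc_aupr(ranking, gold)
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, auroc=auroc, aupr=aupr)
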