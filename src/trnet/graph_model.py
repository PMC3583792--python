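"""Directed-graph containers and file formats.

Two in-memory containers are shared by every algorithm in the package:

* :class:`WeightedDigraph` — an n-by-n matrix of *interaction
  uncertainties* (p-value-like, smaller = more certain) with ``numpy.inf``
  standing for "no edge".  Using infinity makes the required invariant
  "the no-edge sentinel is larger than every finite weight" hold
  unconditionally.
* :class:`UnweightedDigraph` — a boolean adjacency matrix.

Node identity is a string label; indices are assigned 0-based in
first-appearance order and remain stable under every operation.

Supported serialisations are the two formats common in network-inference
benchmarks: a TSV edge list (``source<TAB>target[<TAB>weight]``, the
DREAM ``G1 G2 w`` dialect parses under it) and a dense CSV matrix with
``inf`` marking absent edges.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO, Union

import numpy as np

__all__ = [
    "NO_EDGE",
    "WeightedDigraph",
    "UnweightedDigraph",
    "Thresholds",
    "GraphFormatError",
    "read_graph",
    "write_graph",
    "as_unweighted",
]

#: Sentinel for an absent edge.  Strictly greater than any finite weight.
NO_EDGE: float = np.inf


class GraphFormatError(ValueError):
    """Raised when an input stream cannot be parsed into a graph."""


def _check_labels(labels: Sequence[str]) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(x for x in labels if x in seen or seen.add(x))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate node label {dup!r}")
    return labels


@dataclass
class WeightedDigraph:
    """Directed graph with one uncertainty value per edge.

    Parameters
    ----------
    node_labels:
        Unique identifiers; their order fixes the 0-based node indices.
    weights:
        n-by-n float matrix; entry ``(i, j)`` is the uncertainty of edge
        ``i -> j`` or :data:`NO_EDGE` if the edge is absent.
    """

    node_labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.node_labels = _check_labels(self.node_labels)
        w = np.asarray(self.weights, dtype=float)
        n = len(self.node_labels)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} does not match {n} labels")
        if np.isnan(w).any():
            raise ValueError("weights may not contain NaN")
        self.weights = w

    # -- basic queries -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.node_labels)

    @property
    def edge_mask(self) -> np.ndarray:
        """Boolean matrix, True where an edge exists."""
        return np.isfinite(self.weights)

    @property
    def n_edges(self) -> int:
        return int(self.edge_mask.sum())

    def index(self, label: str) -> int:
        return self.node_labels.index(label)

    def weight(self, source: str, target: str) -> float:
        return float(self.weights[self.index(source), self.index(target)])

    def has_edge(self, source: str, target: str) -> bool:
        return np.isfinite(self.weights[self.index(source), self.index(target)])

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield ``(source, target, weight)`` in (i, j) index order."""
        for i, j in zip(*np.nonzero(self.edge_mask)):
            yield self.node_labels[i], self.node_labels[j], float(self.weights[i, j])

    def copy(self) -> "WeightedDigraph":
        return WeightedDigraph(list(self.node_labels), self.weights.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedDigraph):
            return NotImplemented
        return self.node_labels == other.node_labels and np.array_equal(
            self.weights, other.weights
        )

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        nodes: Sequence[str] = (),
    ) -> "WeightedDigraph":
        """Build a graph from ``(source, target, weight)`` triples.

        Node order is first appearance: explicitly listed ``nodes`` first,
        then sources/targets in edge order.
        """
        labels: list[str] = []
        pos: dict[str, int] = {}

        def intern(lab: str) -> int:
            if lab not in pos:
                pos[lab] = len(labels)
                labels.append(lab)
            return pos[lab]

        for lab in nodes:
            intern(str(lab))
        triples = [(intern(str(u)), intern(str(v)), float(w)) for u, v, w in edges]
        wmat = np.full((len(labels), len(labels)), NO_EDGE)
        for i, j, w in triples:
            if np.isfinite(wmat[i, j]) and wmat[i, j] != w:
                raise GraphFormatError(
                    f"conflicting weights for edge {labels[i]!r} -> {labels[j]!r}: "
                    f"{wmat[i, j]} vs {w}"
                )
            wmat[i, j] = w
        return cls(labels, wmat)


@dataclass
class UnweightedDigraph:
    """Directed graph as a boolean adjacency matrix."""

    node_labels: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.node_labels = _check_labels(self.node_labels)
        a = np.asarray(self.adjacency, dtype=bool)
        n = len(self.node_labels)
        if a.shape != (n, n):
            raise ValueError(f"adjacency shape {a.shape} does not match {n} labels")
        self.adjacency = a

    @property
    def n(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def index(self, label: str) -> int:
        return self.node_labels.index(label)

    def has_edge(self, source: str, target: str) -> bool:
        return bool(self.adjacency[self.index(source), self.index(target)])

    def edges(self) -> Iterator[tuple[str, str]]:
        for i, j in zip(*np.nonzero(self.adjacency)):
            yield self.node_labels[i], self.node_labels[j]

    def copy(self) -> "UnweightedDigraph":
        return UnweightedDigraph(list(self.node_labels), self.adjacency.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UnweightedDigraph):
            return NotImplemented
        return self.node_labels == other.node_labels and np.array_equal(
            self.adjacency, other.adjacency
        )

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Sequence[str] = ()
    ) -> "UnweightedDigraph":
        wg = WeightedDigraph.from_edges(((u, v, 1.0) for u, v in edges), nodes)
        return as_unweighted(wg)

    def as_weighted(self, weight: float = 1.0) -> WeightedDigraph:
        """View as a weighted graph with a constant uncertainty per edge."""
        w = np.where(self.adjacency, float(weight), NO_EDGE)
        return WeightedDigraph(list(self.node_labels), w)


@dataclass(frozen=True)
class Thresholds:
    """Lower/upper uncertainty cut-offs for weighted reduction.

    Edges with weight <= ``t_low`` are unconditionally kept; edges with
    weight >= ``t_up`` are unconditionally removed.  ``None`` disables a
    threshold (lower behaves as -inf, upper as the no-edge sentinel).
    """

    t_low: float | None = None
    t_up: float | None = None

    def __post_init__(self) -> None:
        if self.t_low is not None and self.t_up is not None:
            if not self.t_low < self.t_up:
                raise ValueError(
                    f"t_low ({self.t_low}) must be strictly below t_up ({self.t_up})"
                )

    @property
    def low(self) -> float:
        """Effective lower threshold (-inf when disabled)."""
        return -np.inf if self.t_low is None else float(self.t_low)

    @property
    def up(self) -> float:
        """Effective upper threshold (NO_EDGE when disabled)."""
        return NO_EDGE if self.t_up is None else float(self.t_up)


DISABLED = Thresholds()

Graph = Union[WeightedDigraph, UnweightedDigraph]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_edge_list(stream: TextIO, weighted: bool):
    nodes: list[str] = []
    edges: list[tuple[str, str, float]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            # optional isolated-node declaration: "#nodes: a b c"
            body = line[1:].strip()
            if body.lower().startswith("nodes:"):
                nodes.extend(body[len("nodes:"):].split())
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 2:
            u, v = parts
            w = 1.0
        elif len(parts) == 3:
            u, v, ws = parts
            try:
                w = float(ws)
            except ValueError:
                raise GraphFormatError(
                    f"line {lineno}: non-numeric weight {ws!r}"
                ) from None
            if not np.isfinite(w):
                raise GraphFormatError(f"line {lineno}: weight must be finite, got {ws}")
        else:
            raise GraphFormatError(
                f"line {lineno}: expected 2 or 3 fields, got {len(parts)}"
            )
        edges.append((u, v, w))
    g = WeightedDigraph.from_edges(edges, nodes)
    return g if weighted else as_unweighted(g)


def _parse_matrix(stream: TextIO, weighted: bool):
    rows = []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([c.strip() for c in line.split(",")])
    if not rows:
        g = WeightedDigraph([], np.zeros((0, 0)))
        return g if weighted else as_unweighted(g)

    def is_num(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    # an empty corner cell marks a label header; otherwise fall back on
    # the first row being non-numeric
    has_header = rows[0][0] == "" or not all(is_num(t) for t in rows[0])
    if has_header:
        header = rows[0]
        body = rows[1:]
        # header may or may not carry a leading corner cell for the label column
        labels = header[1:] if len(header) == len(body[0]) else header
        data_rows = [r[1:] if len(r) == len(labels) + 1 else r for r in body]
    else:
        labels = [str(i + 1) for i in range(len(rows))]
        data_rows = rows
    n = len(labels)
    if len(data_rows) != n or any(len(r) != n for r in data_rows):
        raise GraphFormatError(
            f"matrix is not square: {n} labels vs {len(data_rows)} rows"
        )
    w = np.empty((n, n))
    for i, r in enumerate(data_rows):
        for j, tok in enumerate(r):
            try:
                w[i, j] = float(tok)
            except ValueError:
                raise GraphFormatError(
                    f"non-numeric matrix entry {tok!r} at row {i + 1}, column {j + 1}"
                ) from None
    if np.isnan(w).any():
        raise GraphFormatError("matrix contains NaN entries")
    g = WeightedDigraph(labels, w)
    return g if weighted else as_unweighted(g)


def read_graph(
    stream: TextIO | str,
    format: str = "edge_list",
    weighted: bool = True,
) -> Graph:
    """Read a directed graph from a text stream or string.

    Parameters
    ----------
    stream:
        File-like object or the raw text itself.
    format:
        ``"edge_list"`` (TSV ``source target [weight]``, ``#`` comments
        ignored, an optional ``#nodes: a b c`` line declares isolated
        nodes) or ``"matrix"`` (CSV, optional label header/column,
        ``inf`` = no edge).
    weighted:
        When False the result is an :class:`UnweightedDigraph`; any
        weights present are discarded.

    An empty stream yields the 0-node graph.  Duplicate edge rows with
    identical weight are tolerated; conflicting weights raise
    :class:`GraphFormatError`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    if format == "edge_list":
        return _parse_edge_list(stream, weighted)
    if format == "matrix":
        return _parse_matrix(stream, weighted)
    raise ValueError(f"unknown format {format!r}")


def write_graph(graph: Graph, stream: TextIO, format: str = "edge_list") -> None:
    """Write a graph so that :func:`read_graph` reproduces it exactly.

    Edge-list rows are emitted in (i, j) index order; isolated nodes are
    declared on a ``#nodes:`` comment line so that round-trips preserve
    the node set.
    """
    weighted = isinstance(graph, WeightedDigraph)
    mask = graph.edge_mask if weighted else graph.adjacency
    if format == "edge_list":
        # the header pins both isolated nodes and the index order
        if graph.n > 0:
            stream.write("#nodes: " + " ".join(graph.node_labels) + "\n")
        for i, j in zip(*np.nonzero(mask)):
            u, v = graph.node_labels[i], graph.node_labels[j]
            if weighted:
                stream.write(f"{u}\t{v}\t{float(graph.weights[i, j])!r}\n")
            else:
                stream.write(f"{u}\t{v}\n")
    elif format == "matrix":
        if graph.n == 0:
            return
        w = graph.weights if weighted else np.where(mask, 1.0, NO_EDGE)
        stream.write("," + ",".join(graph.node_labels) + "\n")
        for i, lab in enumerate(graph.node_labels):
            cells = ["inf" if not np.isfinite(x) else repr(float(x)) for x in w[i]]
            stream.write(lab + "," + ",".join(cells) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def as_unweighted(g: WeightedDigraph) -> UnweightedDigraph:
    """Forget weights: adjacency is True exactly where an edge exists."""
    return UnweightedDigraph(list(g.node_labels), g.edge_mask.copy())
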