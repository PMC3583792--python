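"""Unweighted reduction of a cyclic graph via SCC condensation.

In an unweighted graph an edge is redundant when an indirect simple
path connects the same pair.  Cycles need care: the walk a,b,a,c is
longer than one edge but revisits a, so it is no alternative for the
edge (a,c).  Contracting strongly connected components first makes the
remaining graph acyclic; the component DAG is reduced and the
components re-expanded untouched.
"""

import trnet
from trnet.scc import condense

graph = trnet.UnweightedDigraph.from_edges(
    [("a", "b"), ("b", "a"), ("a", "c")]
)

c = condense(graph)
print("components:", [sorted(graph.node_labels[i] for i in comp)
                      for comp in c.components])
print("component DAG edges:", c.dag.n_edges)

reduced = trnet.tr_unweighted(graph)
print("edges after reduction:", sorted(reduced.edges()))
print("(a,c) survives: the only walks around it revisit node a.")

# a genuinely redundant edge, for contrast
dag = trnet.UnweightedDigraph.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
print("acyclic triangle reduces to:", sorted(trnet.tr_unweighted(dag).edges()))
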