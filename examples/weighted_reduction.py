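"""Weighted transitive reduction of a small uncertainty-weighted graph.

A 4-node chain 1 -> 2 -> 3 -> 4 (uncertainties 0.1, 0.3, 0.2) carries two
shortcut edges (1,4) at 0.5 and (2,4) at 0.8.  The best indirect route
to node 4 has minimax uncertainty 0.3 — strictly more certain than
either shortcut — so the reduction removes both and keeps the chain.
"""

import trnet

graph = trnet.read_graph(
    "1\t2\t0.1\n"
    "2\t3\t0.3\n"
    "2\t4\t0.8\n"
    "1\t4\t0.5\n"
    "3\t4\t0.2\n"
)

h = trnet.minimax_uncertainty(graph)
print("best path uncertainty 1->4:", h.values[graph.index("1"), graph.index("4")])
print("best path uncertainty 2->4:", h.values[graph.index("2"), graph.index("4")])

reduced = trnet.tr_weighted(graph)
print("kept edges (source, target, uncertainty):")
for u, v, w in reduced.edges():
    print(f"  {u} -> {v}  {w}")
print(f"{graph.n_edges - reduced.n_edges} edges removed: each had a strictly "
      "more certain indirect route.")
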