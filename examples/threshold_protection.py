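"""Lower/upper thresholds refine which edges the reduction may touch.

Edges at or below t_low are unconditionally kept — measured with high
certainty, they must survive even when a more certain indirect route
exists.  Protection also hides those routes from other pairs: here
t_low = 0.5 protects (b,c), so the best *visible* alternative for (d,c)
has uncertainty 0.5 instead of the true 0.3.  The final decisions are
nonetheless correct: (d,c) at 0.6 is still beaten and removed, while a
variant at 0.4 is itself protected and kept.
"""

import trnet

edges = [("d", "b", 0.1), ("b", "a", 0.2), ("a", "c", 0.3),
         ("b", "c", 0.5), ("d", "c", 0.6)]
graph = trnet.WeightedDigraph.from_edges(edges, nodes=["a", "b", "c", "d"])
t = trnet.Thresholds(t_low=0.5)

h = trnet.minimax_uncertainty(graph, t)
d, c = graph.index("d"), graph.index("c")
print("visible alternative for d->c under protection:", h.values[d, c])

for w_dc in (0.6, 0.4):
    g = graph.copy()
    g.weights[d, c] = w_dc
    kept = {(u, v) for u, v, _ in trnet.tr_weighted(g, t).edges()}
    verdict = "kept" if ("d", "c") in kept else "removed"
    print(f"w(d,c) = {w_dc}: edge {verdict} "
          f"({'protected by t_low' if w_dc <= 0.5 else 'beaten by a better path'})")
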