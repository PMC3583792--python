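# Methods

## Model

A biological network is a directed graph `G = (V, E, w)` over `n` genes.
The weight `w(e)` of an edge is its *interaction uncertainty* — a
p-value-like score from the statistical post-processing of perturbation
experiments, in `[0, 1]`, smaller meaning more certain. Absent edges
are represented by the sentinel `NO_EDGE = +inf`, which satisfies the
required invariant "sentinel > every finite weight" unconditionally
(a finite sentinel would need re-checking after every operation).

The uncertainty of a path is its weakest link, `W(P) = max_{e∈P} w(e)`,
and `h(i, j) = min_P W(P)` is the minimal transitive interaction
uncertainty over all paths `i → j`. Since the single edge `(i, j)` is
itself a path, `h(i, j) ≤ w(i, j)` always. The weighted transitive
reduction keeps exactly the edges with `w(e) = h(e)`; kept edges keep
their weights. Ties are kept deliberately: removal demands a *strictly*
more certain alternative, which also makes the reduction the identity
map on graphs whose weights are all equal.

Cycles are harmless for the weighted reduction: inserting a cycle into
a path can only raise (never lower) its maximum weight, so minimax
search ignores cycles automatically. The same is *not* true of
unweighted reduction, where a closed walk such as a→b→a→c is no
substitute for the edge (a, c); see "Cyclic unweighted graphs" below.

## Thresholds

Two optional cut-offs refine the removal rule, required to satisfy
`t_low < t_up` when both are enabled:

* `t_low` (default disabled, behaves as −inf): edges with `w ≤ t_low`
  are unconditionally kept. Measured-with-high-certainty interactions
  must not be sacrificed to an indirect explanation. Protection has a
  side effect: a protected edge's entry is never improved during the
  sweep, so *intermediate* all-pairs values can be larger than the true
  `h` (the protected edge hides better routes passing through it). The
  final keep/remove decisions are nonetheless correct — any pair whose
  direct edge is beaten by a hidden route is also beaten by a visible
  one — a claim we do not prove formally but verify against the
  definition-based oracle on randomized fixtures with randomized
  thresholds; a counterexample would surface as a test failure.
* `t_up` (default disabled, behaves as the no-edge sentinel): edges
  with `w ≥ t_up` are unconditionally removed. This filter is
  independent of the reduction and commutes with it (checked as an
  algebraic property test), so it may run before or after.

## The sweep

All-pairs minimax uncertainties are computed by a Floyd–Warshall
variant in (min, max) algebra over the weight matrix `B` (initialised
with `w`, `inf` for non-edges). For each pivot `k`, every pair `(i, j)`
is offered the route `i → k → j` at uncertainty
`max(B[i,k], B[k,j])`; the entry is overwritten when that is strictly
smaller and the pair is not `t_low`-protected. A separate boolean
*deletion marker* table records every overwrite. The marker replaces
the sign-bit trick of storing `−viaK`: negating a weight of exactly 0
cannot encode deletion without distinguishing signed zero, while a
marker table is contract-equivalent and robust at `w = 0`. Markers are
set for overwritten direct edges (doomed, but their improved magnitude
must stay visible to later pivots) and for non-edge pairs that gained a
path; after the sweep, the reduction drops every marked edge plus those
at or above `t_up`.

The inner double loop is vectorised: the update for pivot `k` reads
only row `k` and column `k`, and no entry of that row or column can
shrink during its own pivot iteration (`max(x, B[k,k]) < x` is
impossible), so the one-shot vectorised update equals any sequential
inner ordering. The final edge set is also invariant under the *outer*
pivot order; intermediate values are order-dependent only when `t_low`
protection is active. Both invariances are tested against a literal
element-at-a-time reference with shuffled loop orders.

Comparisons are exact — no epsilon. `h` is produced purely by min/max
over input weights, so `w(e) = h(e)` compares bit-identical doubles and
the oracle equivalence tests assert exact equality.

Complexity is `O(n³)` time and `O(n²)` memory; a 1000-node dense sweep
is a few seconds of numpy on one core (exercised as a completion check,
not a timing claim).

Self-loops: the acyclic routine rejects them; the cyclic unweighted
routine absorbs them into their SCC; the weighted sweep treats diagonal
entries like any other pair, so a self-loop is removed exactly when a
strictly more certain cycle through other nodes exists.

## Cyclic unweighted graphs

For acyclic graphs the reduction is the unique minimal subgraph with
the same transitive closure, obtained by deleting every edge bypassed
by an indirect path; the implementation bounds path lengths at two
(only existence matters) in the same Floyd–Warshall shape. Cyclic
reductions are neither unique nor in general subgraphs of the input, so
the package does not attempt them directly: strongly connected
components are contracted (SCC partition from scipy's graph machinery,
renumbered deterministically by first member in index order), the
component DAG is reduced, and components are re-expanded exactly as
they were. For a surviving component-DAG edge the expansion keeps *all*
original inter-component edges (`expand_policy="all"`); this preserves
the closure — verified against brute-force reachability — at the cost
of minimality, and a `"first"` policy (one representative edge, index
order) is available where a sparser output matters. Intra-component
edges are never touched.

## Synthetic benchmark

The generator emulates what a knockout screen sees. A true network is a
seeded random digraph — `dag` (edges only from lower to higher index,
per-pair probability = `density`), `erdos_renyi` (each ordered pair
independently), or `scale_free` (directed preferential attachment;
`density` does not apply) — with uniform(0, 1) edge uncertainties,
transitively reduced so it is its own fixed point. The perturbation
graph keeps every true edge at its weight and adds, for each reachable
non-adjacent ordered pair (diagonal excluded), an edge at
`h(i, j) + eps`: indirect influences are visible but slightly less
certain than their best explanation. Defaults `eps = 0.05`,
`density = 0.1–0.2`, `n = 10–30` for benchmarks. Because every added
edge is strictly less certain than its best indirect route, the
weighted reduction recovers the true network *exactly* when no other
noise is present — a deterministic test of the reconstruction claim
rather than a statistical one. `spurious_rate` flips that fraction of
the remaining non-pairs to uniform-weight noise edges, degrading
recovery gracefully.

What this does not emulate: real expression dynamics, measurement
correlation structure, signed (activating/repressing) interactions, or
the weight distributions produced by moderated statistics on real
knockout data. Passing tests show the reduction machinery is correct
and beneficial under the closure-plus-noise model; they do not certify
reconstruction quality on any particular experimental pipeline.

Evaluation follows the DREAM-challenge recipe: candidate edges are
ranked in three blocks — accepted by the reduction; accepted by the
first filtering step but cut by the reduction; never accepted — blocks
1–2 sorted by uncertainty (ascending by default, because smaller
p-value-like weights mean higher confidence; a descending flag covers
correlation-like scores), ties broken by index, block 3 in index order
(the field's tooling does not fix an order for never-accepted pairs;
index order is this package's convention). AUROC is the trapezoidal
area over that ranking (equivalently the Mann–Whitney probability that
a random true edge precedes a random non-edge, checked against a
brute-force pairwise count) and AUPR is step-wise average precision;
both via scikit-learn. Confusion counts run over ordered off-diagonal
pairs, so `tp + tn + fp + fn = n(n−1)` always.

## Interfaces and conventions

Edge lists are TSV (`source target [weight]`), `#` comments ignored; an
optional `#nodes:` line declares the node set — the only way to carry
isolated nodes and a fixed index order through a file, and written by
default. Matrices are CSV with an optional label header/column and
`inf` for absent edges. Duplicate edge rows with identical weight are
idempotent; conflicting weights are an error naming the edge — failing
loudly beats silently picking one. The CLI (`trnet reduce | simulate |
evaluate`) is a thin wrapper: exit 0 on success, 1 on data errors, 2 on
usage errors, with a stderr log of node/edge counts, removals split by
cause (threshold vs indirect path — useful when tuning thresholds,
which typically takes a few tries) and wall time. Identical
configurations and seeds give byte-identical outputs.

## Known limitations

* Signed interactions are deliberately out of scope; the weighted
  criterion ignores regulation direction (activation/repression), and
  the lower threshold is the pragmatic guard against removing a direct
  edge that only an opposite-signed indirect path "explains".
* The correctness of final removals under `t_low` protection rests on
  empirical verification, not proof (above).
* Cyclic unweighted reduction is closure-preserving but not minimal
  (expansion keeps all inter-component edges by default).
* `brute_force_h` enumerates simple paths and is guarded to n ≤ 12; it
  exists as a test oracle, not an API for real inputs.
* Alternative path-weight operators (sum, product) are not provided.
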