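# Methods

## The network model

`adiponet` models literature-curated adipokine biology as a directed,
signed, six-layer graph. Node categories: `physiologic_perturbation`,
`sleep_disturbance`, `adipokine`, `molecular_target`,
`physiologic_function`, `disease_process`. Edges carry a sign
(`positive`, `negative`, `uncertain`) describing the reported direction
of association; signs are labels, never weights.

Admissible layer transitions are closed-world: perturbation→adipokine,
sleep→adipokine, adipokine→target, target→function, function→disease,
plus the two "shortcut" transitions adipokine→function and
adipokine→disease used when a relation is reported without an
identified mediating mechanism. Any other ordered category pair is a
schema violation. The table is a single constant
(`adiponet.schema.ALLOWED_TRANSITIONS`) that a curator can extend (for
example with target→disease relations) by passing their own set to
`validate`. Two structural consequences follow and are tested as
invariants: perturbation and sleep nodes have in-degree 0, disease
nodes out-degree 0, and all three layers have betweenness exactly 0.

Entity names are case-preserving for display but compared
case-insensitively after whitespace collapsing; this is the most
conservative merge rule short of synonym resolution, which is out of
scope.

### Construction and conflict handling

`build_network` deduplicates assertions per ordered pair. An
`uncertain` sign never conflicts with a definite one — the definite
sign wins — while a pair asserted both `positive` and `negative` is a
contradiction. Two policies resolve contradictions, both logged as
`ConflictRecord`s: `drop_edge` (default) removes only the contradictory
edge; `exclude_node` additionally removes the node on a configurable
side (default: target) with all its incident edges, mirroring the
stricter curation practice of discarding entities with inconsistent
reported relations. Construction is order-invariant: permuting the
input rows yields an identical network and conflict log (canonical
display spelling is the lexicographically smallest variant seen).

No transitive reduction is performed: shortcut edges coexist with the
mechanistic chains they parallel, which keeps coverage of relations
whose mechanism is unknown.

## Centrality

Degree centrality is the raw count `C_i = deg(i)`, split into in- and
out-degree. Betweenness is computed on the directed, unweighted graph
without normalization:

    C_bet(i) = Σ_{x≠y≠i, σ_xy>0} σ_xy(i) / σ_xy

with endpoints excluded from `σ_xy(i)` (interior-node convention) and
unreachable pairs contributing nothing. No connectivity requirement is
imposed. A `normalized=True` flag divides by `(n−1)(n−2)` for
cross-tool comparison.

Two independent implementations coexist deliberately:

* `betweenness` — single-source BFS with dependency back-propagation
  (the Brandes accumulation scheme), O(|V|·|E|);
* `betweenness_oracle` — exhaustive enumeration of all shortest paths
  per ordered pair over the shortest-path DAG, counting interior-node
  passages directly.

The test suite requires agreement to 1e-9 per node on 200 random
layered networks and on all pedagogical fixtures, and additionally
cross-checks against networkx's implementation; closed forms (chain
interior node k of an n-chain: `(k−1)(n−k)`; diamond: 0.5/0.5; complete
digraph: all zeros) pin the conventions. Source iteration is in sorted
node order so floating-point accumulation is bit-reproducible. Ranks
are ordinal (1..n), descending by value, ties broken lexicographically
by node name.

## Classification

The field's definitions of hub and bottleneck are qualitative; the
package makes them operational with nearest-rank quantile cutoffs that
are always reported next to the resulting sets:

* **hubs**: degree ≥ the 0.90 nearest-rank quantile of the degree
  multiset, and degree ≥ 1 (the extra floor prevents the degenerate
  edge-free network from classifying every isolated node as a hub);
* **bottlenecks**: betweenness ≥ the 0.90 quantile of the
  *positive*-betweenness values (empty when nothing has positive
  betweenness);
* **nonhub bottlenecks**: bottlenecks with degree ≤ the 0.50 quantile
  of the *distinct* observed degree values, minus any hubs.

The low-degree cutoff deliberately uses distinct values rather than the
degree multiset: layered curated networks carry a large mass of leaf
nodes (degree 1), and a multiset median would fall below any node that
has both an in- and an out-edge — including the canonical low-degree
bridge that the class exists to describe. On the 9-node bridged
double-star (degrees 1×6, 2, 4, 4) the distinct-value median is 2 and
correctly admits the degree-2 bridge; the multiset median of 1 would
not. All three quantile parameters are configurable in the API and CLI.

`degree_distribution` reports the exact degree histogram, the
least-squares slope of log(count) vs log(degree) over observed degrees
≥ 1, and a heavy-tail flag (slope ≤ −1 and max degree ≥ 4× median).
The flag is a descriptive heuristic, stated as such: at 94 nodes a
histogram is far too small for rigorous tail fitting, and maximum-
likelihood power-law estimation is out of scope. On default synthetic
networks the hub-dominance half of the heuristic holds strongly
(max/median degree ≈ 14) while the histogram-slope half generally does
not (the mid-degree bulk flattens the fit to ≈ −0.8); the flag is
therefore exercised in tests on constructed histograms (a 10-node star
yields slope −1 and the flag) rather than asserted on the generator's
output.

## The synthetic generator

The generator stands in for a curated network that exists only as a
published figure. Defaults are the study conditions: 94 nodes split as
6 perturbations, 4 sleep disturbances, 6 adipokines, 28 molecular
targets, 25 functions, 25 diseases (only the 94 total and the six
adipokines are externally fixed; the split is an informed choice and is
configuration, not a constant), 264 directed edges, sign probabilities
0.5/0.3/0.2 (positive/negative/uncertain), Zipf exponent 1.6 over
adipokine attachment ranks, 20% of the budget spent on shortcut edges.

Procedure, fully deterministic given the seed (one numpy Generator is
the only randomness source):

1. **Planted bridge motif.** Both planted hub adipokines point at one
   designated bridge target, which feeds two reserved functions, which
   feed two reserved diseases; the reserved nodes accept no other
   in-edges, so every path into the motif crosses the bridge. This
   gives the bridge degree 4 and betweenness 48 (12 upstream sources ×
   4 reserved destinations) — the low-degree/high-betweenness
   signature. An earlier single-reserved-disease variant produced
   betweenness 36, which sat on the bottleneck cutoff and made
   recovery of the planted label unreliable; the two-disease motif is
   the calibrated design.
2. **Coverage.** Every node receives at least one incident edge
   (guaranteeing the exact node count), drawn with the same weights as
   the bulk sampling.
3. **Quota fill.** The non-shortcut budget is apportioned across the
   five chain transitions (fractions 0.14/0.09/0.26/0.28/0.23,
   largest-remainder rounding); adipokine endpoints are drawn with
   Zipf(1.6) weights in which the planted hubs hold the top ranks,
   other pools uniformly. Duplicate pairs are resampled (cap 10⁶
   attempts, then a capacity error), so the edge budget is met exactly.
   Zipf weighting is applied to adipokines only: skewing the
   downstream pools as well lowers the median degree below the
   bridge's fixed degree of 4 and destroys bridge recovery, while
   uniform pools keep the median at 4.
4. **Signs** are drawn i.i.d. from the configured probabilities.

Measured over seeds 0–99 at defaults: planted hubs are recovered by
`classify` in 100/100 runs (and hold the top-2 adipokine degrees in
99/100), and the planted bridge is flagged as a nonhub bottleneck in
99/100. The max/median adipokine-degree ratio rises monotonically with
the Zipf exponent (≈ 2.2 / 3.1 / 4.4 at exponents 1.0 / 1.6 / 2.5).

What the generator does **not** emulate: synonym ambiguity, per-edge
evidence strength, correlated curation errors, the true per-layer node
counts of any published network, and realistic within-layer degree
heterogeneity for targets/functions/diseases. Passing tests therefore
demonstrate correctness of the algorithms and calibrated recoverability
of planted structure, not fidelity to any particular curated dataset.

## Robustness

`stability` resamples the network R times: each edge is independently
deleted with probability `edge_drop_prob`, and `Binomial(|E|,
edge_add_prob)` schema-legal absent edges are inserted (sign
`uncertain` — curation noise produces plausible relations, never
schema-violating ones). Classification is recomputed per replicate with
the baseline cutoffs **frozen**, so the reported per-node membership
frequencies measure instability of the network rather than of the
quantile thresholds; `refit_thresholds=True` re-quantiles per replicate
for the alternative reading. At zero noise the report reproduces the
baseline exactly (frequency 1.0 for members, 0.0 otherwise) — this
identity is a test.

## Numerical and interface conventions

* Nearest-rank quantiles everywhere (no interpolation), for platform
  reproducibility.
* Report floats are serialized with 9 significant digits.
* GEXF 1.3 is written directly (networkx's writer targets older GEXF
  drafts); `viz:size` equals the node degree, implementing
  degree-proportional node weighting for Gephi. GraphML export goes
  through networkx.
* CLI exit codes: 0 success, 1 validation failure, 2 usage error; every
  command writes a JSON provenance record (inputs, parameters, seed,
  package version).
* The pedagogical fixtures include a symmetric protein-interaction toy
  stored as reciprocal directed pairs; it predates the layer schema and
  is exempt from transition validation (centrality does not consult
  categories).

## Problem sizes

Default analyses run on the 94-node/264-edge condition. Property
sweeps use 100 seeds at full size for recovery rates and a reduced
46-node/120-edge configuration for the oracle-equivalence and
conservation sweeps, keeping the exhaustive path-enumeration oracle
comfortably fast while exercising the same code paths.

## Known limitations

* No synonym/ontology resolution: "AMPK" and "AMP activated protein
  kinase" are distinct nodes unless normalized upstream.
* Signs are not propagated through paths; betweenness ignores them.
* The heavy-tail diagnostic is heuristic (see above).
* `exclude_node` must guess which endpoint of a contradiction to drop;
  the side is configurable because curation practice varies.
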