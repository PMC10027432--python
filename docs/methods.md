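# Methods

This note records the engine's modeling assumptions, the defaults that
matter, and the choices made where the design space was genuinely open.

## Data model and hierarchy semantics

Knowledge graphs are labeled multigraphs; parallel edges are retained
whenever they differ in predicate or asserting source. Category and
predicate hierarchies are parent-link DAGs (multiple parents allowed, since
mixin-style ontologies are not trees); descendant queries are reflexive
graph reachability. A constraint set is disjunctive and an empty set means
*unconstrained*. Edge identity for deduplication is the quadruple
(subject, object, predicate, primary_source): the same triple asserted by
two sources is two edges, preserving provenance. Attribute conflicts during
merges resolve first-writer-wins — a simple, order-deterministic rule; no
attempt is made to reconcile contradictory numeric annotations from
different providers.

## Synonymizer

Identifier equivalence is a disjoint-set closure over pairwise assertions
(same-as edges, external cluster files, byte-identical node names), with a
semantic-type guard: a merge is applied only when the two sides' category
profiles share a term after expanding each profile to its ancestor closure,
*excluding the category root* — "everything is a NamedThing" can never
justify a merge. All assertion kinds carry equal weight; the guard, not
evidence precedence, is what blocks bad merges. Cluster representatives are
chosen by a configurable CURIE-prefix priority (disease/ontology prefixes
first, default `MONDO > DOID > ORPHANET > ...`), tie-broken
lexicographically, so canonicalization is deterministic. Canonicalizing a
graph re-points edges, merges cluster members (canonical member's name
wins), deduplicates by edge identity and keeps self-loops created by
merging — applying it twice equals applying it once.

## Expansion and pruning

Query edges are processed breadth-first in a deterministic order: most
pinned/already-fulfilled endpoints first, then fewer constraint categories,
then key. Provider routing is by meta-triple matching under hierarchy
expansion, in either orientation. Lookups are batched (one request carries
all candidate ids for the anchored side) and the merged answer must be
independent of provider order; each provider gets a wall-clock budget
(`kp_timeout`, default 30 s) enforced by a worker thread — an overrunning
provider is abandoned for that query edge with a warning (its thread is
orphaned, which is acceptable for in-process providers).

Per-query-edge prune thresholds adapt to the constraint profile: 5000 when
both endpoints are pinned, 100 when every constraint term is a namespace
root or absent, 200 when an unpinned endpoint uses a *prevalent* category
(default: all categories one generation below the root, overridable), 500
otherwise; an explicit `prune_threshold` overrides all. When a query edge's
triples exceed the threshold, candidate nodes on the growing side are scored
by the two-sided Fisher exact p-value of their connectivity to the anchored
side in the background graph (the union of all providers' graphs,
canonicalized), converted to a unit score by the ranker's p-value sigmoid,
and retained in descending score — ties by ascending CURIE — until the next
candidate would push the triple count past the threshold. Removed nodes
trigger constraint propagation to a fixpoint (edges and nodes that lose all
query support are dropped). Backtracking into pruned-away answers when a
later query edge fails is deliberately not implemented.

## Overlay statistics

**Fisher exact enrichment.** For a subject binding {v_s} and object
candidate v_o, the 2×2 table splits a population by adjacency to v_o (rows)
and membership in {v_s} (columns). The population is the set of background
nodes sharing a category with the subject binding, excluding v_o. The
engine's own source text for this statistic is ambiguous about which side's
category defines the population; the subject-side reading is used because
the object-side reading makes every table degenerate (the subject set would
fall outside the population, forcing a = 0) and defeats the statistic's
purpose. The p-value is the standard two-sided convention (sum of
margin-preserving table probabilities not exceeding the observed one),
computed via `scipy.stats.fisher_exact` and verified in the test suite
against an exact-rational enumeration oracle on all tables with total ≤ 30.

**Jaccard neighbor sharing.** JS(v_s, v_e) = n / Deg(v_s), where Deg(v_s)
counts distinct neighbors of v_s in the background graph belonging to the
requested intermediate category (hierarchy-expanded) and n counts those also
adjacent to v_e. The graph is treated as undirected and edge multiplicity is
ignored, guaranteeing JS ∈ [0, 1]; the degree is taken in the background
graph restricted to the intermediate category. Alternative readings (answer
KG degree; unrestricted degree) would not bound the ratio by 1. Zero
qualifying neighbors yields a missing value (NaN), not 0.

**Normalized co-occurrence distance.**
NGD(t1,t2) = [max(log f1, log f2) − log f12] / [log N − min(log f1, log f2)]
over a local term/pair count index keyed by exact, case-sensitive node name.
The min term in the denominator is min over the *term frequencies* (a
log-ratio, hence base-invariant). Undefined cases — absent terms, zero
counts, zero co-occurrence — return the missing sentinel and produce no
virtual edge.

**Predictors.** Link-prediction scores (e.g. drug-treats-disease
probability) enter through a callable contract `(subject, object) -> float`;
the package ships a deterministic constant stub only — training embedding
models is out of scope.

Virtual edges never fulfill original query edges; each overlay invocation
allocates a fresh virtual key (v0, v1, ... in creation order) and never
mutates or deletes existing edges.

## Filtering

Thresholds use strict inequality; targets lacking the named attribute are
retained (overlays are opt-in, so absence of an annotation is not evidence
against an edge). Pinned nodes are never removed. Because removal can
invalidate previously enumerated results, `filter_kg` clears them with a
warning; re-run `resultify`.

## Result enumeration

A result is a distinct node-binding map; all qualifying KG edges (including
parallel ones) are grouped under the query edge key, so two bindings
differing only in edge selection are one result. Two query nodes may bind
the same KG node by default (`strict_injective=False` — nothing in the
fulfillment semantics forbids it; the option documents the alternative).
Enumeration is backtracking over query nodes in ascending candidate-set
order with forward constraint checking; correctness is defined by the
declarative checker `binding_fulfills` and enforced in tests by exhaustive
oracle comparison on random worlds (≥100 seeded KG/query pairs, including
cycles and parallel query edges, under both direction modes).

## Ranking

Edge confidence is the product of sigmoid-normalized recognized scalar
attributes times the publication-count transform 1/(1 + (b/n)^a) with
a = log₂9 and b = 4 — the unique parameterization passing both calibration
points (n=4 ↦ 0.5, n=8 ↦ 0.9); n = 0 scores 0. The transform is applied to
any `publications` attribute regardless of asserting source. Default sigmoid
parameters are this package's choices and are config-overridable:
`fisher_exact_p` is scored on −log₁₀p with midpoint 10⁻⁵ and one-decade
width; `ngd` is descending with midpoint 0.6, width 0.1; `jaccard_index`
and `probability_treats` map identically (clipped to [0,1]); unrecognized
attributes contribute nothing, and an edge with no recognized attributes
gets the base score (default 0.5).

Graph metrics are computed on the result's bound subgraph with parallel-edge
confidences summed per node pair: undirected max-flow and longest-geodesic
weight are maximized over terminal pairs — terminals are the bindings of
degree-1 query nodes, falling back to all bound pairs for cycle queries —
and the Frobenius norm is the 2-norm of the per-pair weight vector. Geodesic
weight is the *sum* of edge confidences along a minimum-hop path, ties among
geodesics broken by maximum total weight. Final scores are fractional
(mean-of-ties) descending ranks on the three metrics, averaged and
normalized to (N − r̄)/(N − 1); a single result scores 1.0; ties in final
score order by node-binding signature so runs are reproducible.

## Synthetic world

The generator emulates, at desk scale, the structures each stage consumes:
a small category/predicate hierarchy (depth 3 / 3); a provider bundle whose
graph contains a pinned drug interacting with s = 6 designated subject
proteins (out of 20); a planted hub disease associated with m = 5 of those
subjects — the enrichment signal the Fisher overlay and pruning must
recover — against distractor diseases attached to one protein each (half to
subject proteins, half to others, so pruning faces live alternatives);
synonym clusters realized as duplicate disease identifiers chained by
same-as assertions; per-edge publication lists drawn from a zero-inflated
geometric distribution (inflation 0.5, mean 3 — chosen so the calibrated
publication transform spreads edge scores across (0,1)); and a co-occurrence
index where the drug–subject name pairs receive pair counts at 0.8 of the
smaller term count against sparse unit-count background pairs. All
randomness flows from one integer seed through one generator; outputs are
byte-identical across runs.

What the synthetic world does **not** model: realistic degree distributions
and graph scale, noisy or conflicting cross-vocabulary mappings, predicate
qualifiers, literature-index biases, or trained link-prediction signal.
Passing tests therefore demonstrate the correctness of the machinery —
matching semantics, statistics, pruning and ranking arithmetic — not
retrieval quality on production biomedical corpora.

## Numerical and degenerate-input conventions

Fisher p-values are clipped to (0, 1] and compared to the enumeration
oracle at 1e-7 relative tolerance (the conventional tie tolerance for
two-sided tail accumulation). Missing statistics are NaN sentinels, never 0.
Enrichment against a population that coincides with the subject set is
uninformative by construction (all tables have empty complement columns);
pruning then falls back to its deterministic CURIE tie-break. The
publication transform saturates in double precision above roughly 10⁴
publications. Empty overlays, zero-result queries and unfulfillable query
edges are warnings, not errors; expansion with no pinned node is an error.

## Problem sizes

Default tests and the acceptance script run on the generator's default
world (~40 nodes, ~35 edges), random enumeration worlds of ≤ 8 nodes with
≤ 3-edge queries, and exhaustive Fisher verification over all 2×2 tables
with total ≤ 30 — sizes chosen so every oracle can be exhaustive while the
full suite completes in well under a minute of CPU.

## Known limitations

- No live federation, service discovery or remote providers; the provider
  contract is in-process only.
- The query-graph interpreter uses one universal template
  (build → expand → resultify → rank) rather than a curated template
  library; archetype-specific templates would slot in at the same seam.
- No trained drug-treats-disease model; the predictor seam accepts one.
- Result-set (`is_set`) grouping semantics and predicate qualifiers are not
  modeled.
- Pruning cannot backtrack: answers discarded at one query edge are not
  revisited if a later edge fails.
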