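# kgreason

A self-contained biomedical knowledge-graph reasoning engine. It answers
graph-patterned questions — *which proteins interact with this drug? which
diseases are enriched among these genes?* — against **local knowledge
providers** (node/edge tables with declared meta-triple capabilities),
with no web-service federation: expansion, statistical overlay, filtering,
exhaustive query-graph fulfillment and multi-metric ranking all run
in-process on data you supply or generate.

It is aimed at computational biologists and translational-informatics
developers who want the analysis machinery of TRAPI/Biolink-style reasoning
engines — hierarchical category/predicate matching, adaptive pruning,
enrichment overlays, subgraph result enumeration, rank-aggregated scoring —
in a reproducible desk-scale package.

## The model

A **knowledge graph** is a labeled multigraph: nodes are concepts with CURIE
identifiers (`MONDO:0019391`) and hierarchical category terms; edges are
subject–predicate–object triples with provenance and attributes. A **query
graph** is a connected constraint pattern: query nodes may be *pinned* to
specific CURIEs or constrained to categories, query edges to predicates.
A subgraph *fulfills* the query graph when every pin, every hierarchy-expanded
category/predicate constraint and the topology are satisfied (a constraint
`interacts_with` is met by any descendant such as
`physically_interacts_with`; edge direction is optionally ignored).

The pipeline:

1. **Expand** — fulfill query edges breadth-first against every provider
   whose meta-triples can answer them, canonicalizing identifiers through a
   synonymizer (disjoint-set clustering of equivalence assertions, guarded
   by semantic-type compatibility) and pruning each query edge's answers to
   an adaptive threshold (5000 doubly-pinned / 100 unconstrained /
   200 prevalent-category / 500 otherwise) using Fisher-exact enrichment
   scores against the background corpus.
2. **Overlay** — attach *virtual edges* carrying context: two-sided Fisher
   exact enrichment p-values; Jaccard-style neighbor sharing
   JS(v_s, v_e) = n / Deg(v_s); the normalized co-occurrence distance
   NGD(t1,t2) = [max(log f(t1), log f(t2)) − log f(t1,t2)] /
   [log N − min(log f(t1), log f(t2))]; or a pluggable link predictor.
3. **Filter** — drop nodes/edges by attribute thresholds; sort/limit results.
4. **Resultify** — enumerate *all* fulfilling subgraphs (backtracking with
   forward constraint propagation; verified against brute-force enumeration).
5. **Rank** — each edge gets a confidence in [0,1]: attribute sigmoids times
   the publication-count transform **1 / (1 + (b/n)^a)** with a = log₂9,
   b = 4, calibrated so 4 publications ↦ 0.5 and 8 ↦ 0.9. Three graph
   metrics (max-flow, Frobenius norm of edge weights, weight of the longest
   minimum-hop geodesic between terminal nodes) are fractionally ranked over
   results and the final score is the mean rank normalized to [0,1].

Workflows are expressed in a small command language
(`add_qnode`, `add_qedge`, `expand`, `overlay`, `filter_kg`,
`filter_results`, `resultify`, `rank_results`), one command per line, e.g.
`add_qnode(ids=[CHEMBL.COMPOUND:CHEMBL112], key=n0)`. A bare JSON query
graph is translated into a workflow by a deterministic template.

## Worked example

Generate a seeded synthetic world and run the bundled reference query
(proteins interacting with the pinned drug):

```sh
kgreason synth --seed 7 --out demo
kgreason run --query demo/query.json --kp demo/kp0 --hierarchy demo \
         --assertions demo/assertions.tsv --out demo/response.json
# wrote demo/response.json: 6 results
```

The response's top bindings:

```
{'n0': 'CHEMBL.COMPOUND:D0000', 'n1': 'UNIPROTKB:P0000'}  score 0.6
{'n0': 'CHEMBL.COMPOUND:D0000', 'n1': 'UNIPROTKB:P0001'}  score 0.6
{'n0': 'CHEMBL.COMPOUND:D0000', 'n1': 'UNIPROTKB:P0003'}  score 0.6
```

Six results — one per protein the drug touches, matching
`expected_result_count` in `demo/manifest.json`. Scores come from the
rank-aggregation step: results whose supporting edges carry more
publications rank higher; here several tie. The same library surface is
available in Python (`kgreason.execute_workflow`,
`kgreason.enumerate_results`, ...), and the synthetic world (planted
enrichment hub, synonym clusters, co-occurrence index) is produced by
`kgreason.generate_synthetic_kg`.

## Layout

- `src/kgreason/hierarchy.py`, `graph.py` — ontology DAGs and the multigraph model
- `src/kgreason/synonymizer.py` — identifier clustering and canonicalization
- `src/kgreason/workflow.py` — command language, query-graph interpreter, executor
- `src/kgreason/expander.py`, `overlay.py`, `filtering.py`, `resultify.py`,
  `ranker.py` — the five analysis stages
- `src/kgreason/providers.py`, `io.py`, `synth.py`, `cli.py` — provider
  contract, file formats, synthetic generator, command line
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
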