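"""Breadth-first query-graph expansion over local knowledge providers.

The expander fulfills one query edge at a time: it routes the edge to every
provider whose advertised meta-triples can satisfy it, issues a batched
one-hop lookup (one request carries all current candidate ids for the pinned
or already-fulfilled side), canonicalizes and merges the returned fragments,
and then prunes the answer set for that query edge down to an adaptive
threshold using Fisher-exact enrichment scores, before moving on to the next
query edge.  Pruning is what keeps multi-hop queries from exploding
combinatorially; its cost is that good answers can be lost, which is why the
threshold adapts to how constrained the query edge is.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor, TimeoutError as FutureTimeout
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .graph import KnowledgeEdge, KnowledgeGraph, merge_graphs
from .hierarchy import CATEGORY, PREDICATE, OntologyHierarchy, term_matches
from .overlay import fisher_enrichment_pvalues
from .providers import EngineConfig, KnowledgeProvider, LookupRequest
from .querygraph import QueryEdge, QueryGraph
from .ranker import RankerConfig, attribute_to_unit_score
from .state import ReasoningState
from .synonymizer import Synonymizer, canonicalize_graph

logger = logging.getLogger(__name__)

# Adaptive prune thresholds per query-edge constraint profile
THRESHOLD_DOUBLY_PINNED = 5000
THRESHOLD_UNCONSTRAINED = 100
THRESHOLD_PREVALENT = 200
THRESHOLD_DEFAULT = 500


def _qedge_constraint_terms(
    qedge: QueryEdge, qg: QueryGraph
) -> Tuple[List[str], List[str]]:
    """(category terms on unpinned endpoints, predicate terms) of a qedge."""
    cats: List[str] = []
    for key in (qedge.subject_key, qedge.object_key):
        qnode = qg.nodes[key]
        if not qnode.is_pinned and qnode.categories:
            cats.extend(qnode.categories)
    preds = list(qedge.predicates or [])
    return cats, preds


def select_providers(
    qedge: QueryEdge,
    qg: QueryGraph,
    providers: Sequence[KnowledgeProvider],
    hierarchy: OntologyHierarchy,
) -> List[KnowledgeProvider]:
    """Providers whose meta-triples can fulfill the query edge.

    A meta-triple matches when its predicate and both endpoint categories
    satisfy the query edge's constraints under hierarchy-aware matching, in
    either subject/object orientation.
    """
    subj = qg.nodes[qedge.subject_key]
    obj = qg.nodes[qedge.object_key]
    subj_cats = [] if subj.is_pinned else list(subj.categories or [])
    obj_cats = [] if obj.is_pinned else list(obj.categories or [])
    preds = list(qedge.predicates or [])

    def triple_matches(mt, s_cats, o_cats) -> bool:
        return (
            term_matches(hierarchy, mt.predicate, preds)
            and term_matches(hierarchy, mt.subject_category, s_cats)
            and term_matches(hierarchy, mt.object_category, o_cats)
        )

    selected = []
    for provider in providers:
        for mt in provider.meta_triples():
            if triple_matches(mt, subj_cats, obj_cats) or triple_matches(
                mt, obj_cats, subj_cats
            ):
                selected.append(provider)
                break
    return selected


def default_prune_threshold(
    qedge: QueryEdge,
    qg: QueryGraph,
    hierarchy: OntologyHierarchy,
    config: EngineConfig,
) -> int:
    """Adaptive per-query-edge prune threshold.

    5000 when both endpoints are pinned; 100 when the edge is unconstrained
    (no category/predicate terms, or only namespace roots); 200 when an
    unpinned endpoint uses a prevalent category; 500 otherwise.  A config
    override wins over all of these.
    """
    if config.prune_threshold is not None:
        return config.prune_threshold
    subj = qg.nodes[qedge.subject_key]
    obj = qg.nodes[qedge.object_key]
    if subj.is_pinned and obj.is_pinned:
        return THRESHOLD_DOUBLY_PINNED
    cats, preds = _qedge_constraint_terms(qedge, qg)
    roots = set(hierarchy.roots.values())
    if all(t in roots for t in cats) and all(t in roots for t in preds):
        return THRESHOLD_UNCONSTRAINED
    prevalent = config.effective_prevalent(hierarchy)
    if any(c in prevalent for c in cats):
        return THRESHOLD_PREVALENT
    return THRESHOLD_DEFAULT


def _expand_pinned_ids(ids: Sequence[str], syn: Optional[Synonymizer]) -> Set[str]:
    """All identifiers equivalent to the given pins (providers may store any
    member of a synonym cluster)."""
    out: Set[str] = set(ids)
    if syn is not None:
        for i in ids:
            cluster = syn.cluster_of(i)
            if cluster is not None:
                out |= set(cluster.members)
            out.add(syn.get_canonical(i))
    return out


def _node_satisfies_qnode(
    node_id: str,
    qnode_key: str,
    qg: QueryGraph,
    kg: KnowledgeGraph,
    state: ReasoningState,
    hierarchy: OntologyHierarchy,
    pinned_sets: Dict[str, Set[str]],
) -> bool:
    qnode = qg.nodes[qnode_key]
    if qnode.is_pinned:
        return node_id in pinned_sets[qnode_key]
    bound = state.qnode_bindings.get(qnode_key)
    if bound:
        return node_id in bound
    node = kg.nodes.get(node_id)
    if node is None:
        return False
    return any(term_matches(hierarchy, c, qnode.categories or []) for c in node.categories)


def _edge_orientations(
    edge: KnowledgeEdge,
    qedge: QueryEdge,
    qg: QueryGraph,
    kg: KnowledgeGraph,
    state: ReasoningState,
    hierarchy: OntologyHierarchy,
    pinned_sets: Dict[str, Set[str]],
) -> List[Tuple[str, str]]:
    """Orientations (as (qnode bound to edge.subject, qnode bound to
    edge.object)) in which the KG edge can fulfill the qedge."""
    if not term_matches(hierarchy, edge.predicate, qedge.predicates or []):
        return []
    out = []
    sk, ok = qedge.subject_key, qedge.object_key
    if _node_satisfies_qnode(
        edge.subject, sk, qg, kg, state, hierarchy, pinned_sets
    ) and _node_satisfies_qnode(edge.object, ok, qg, kg, state, hierarchy, pinned_sets):
        out.append((sk, ok))
    if _node_satisfies_qnode(
        edge.subject, ok, qg, kg, state, hierarchy, pinned_sets
    ) and _node_satisfies_qnode(edge.object, sk, qg, kg, state, hierarchy, pinned_sets):
        if (ok, sk) not in out:
            out.append((ok, sk))
    return out


def _qedge_order(
    qg: QueryGraph, fulfilled: Set[str], state: ReasoningState
) -> List[str]:
    """Deterministic processing order among unprocessed qedges: most
    pinned/already-fulfilled endpoints first, then fewer allowed categories,
    then key."""

    def anchored(qnode_key: str) -> bool:
        qnode = qg.nodes[qnode_key]
        return qnode.is_pinned or bool(state.qnode_bindings.get(qnode_key))

    def sort_key(qedge_key: str):
        e = qg.edges[qedge_key]
        n_anchored = int(anchored(e.subject_key)) + int(anchored(e.object_key))
        n_cats = sum(
            len(qg.nodes[k].categories or [])
            for k in (e.subject_key, e.object_key)
            if not qg.nodes[k].is_pinned
        )
        return (-n_anchored, n_cats, qedge_key)

    return sorted((k for k in qg.edges if k not in fulfilled), key=sort_key)


def _lookup_with_timeout(
    provider: KnowledgeProvider, request: LookupRequest, timeout: float
) -> Optional[KnowledgeGraph]:
    executor = ThreadPoolExecutor(max_workers=1)
    try:
        future = executor.submit(provider.lookup, request)
        return future.result(timeout=timeout)
    except FutureTimeout:
        return None
    finally:
        executor.shutdown(wait=False)


def prune_qedge_answers(
    state: ReasoningState,
    qedge_key: str,
    threshold: int,
    background: KnowledgeGraph,
    growing_qnode_key: Optional[str] = None,
    ranker_config: Optional[RankerConfig] = None,
) -> ReasoningState:
    """Cap the triples fulfilling one query edge at ``threshold``.

    Candidate nodes on the growing (previously unbound) side are scored by
    the Fisher-exact enrichment p-value of their connectivity to the anchored
    side in the background graph, normalized to a unit score; candidates are
    retained in descending score (ties by ascending CURIE) until adding the
    next candidate's triples would exceed the threshold.
    """
    if threshold < 1:
        raise ValueError("prune threshold must be >= 1")
    bound_edges = state.qedge_bindings.get(qedge_key, set())
    if len(bound_edges) <= threshold:
        return state

    qedge = state.query_graph.edges[qedge_key]
    if growing_qnode_key is None:
        subj, obj = (
            state.query_graph.nodes[qedge.subject_key],
            state.query_graph.nodes[qedge.object_key],
        )
        if subj.is_pinned and not obj.is_pinned:
            growing_qnode_key = qedge.object_key
        elif obj.is_pinned and not subj.is_pinned:
            growing_qnode_key = qedge.subject_key
        else:
            growing_qnode_key = qedge.object_key
    anchored_key = (
        qedge.subject_key if growing_qnode_key == qedge.object_key else qedge.object_key
    )

    kg = state.answer_kg
    candidate_edges: Dict[str, Set[str]] = {}
    for eid in bound_edges:
        edge = kg.edges[eid]
        for endpoint in (edge.subject, edge.object):
            if endpoint in state.qnode_bindings.get(growing_qnode_key, set()):
                candidate_edges.setdefault(endpoint, set()).add(eid)

    anchored_nodes = set(state.qnode_bindings.get(anchored_key, set()))
    pvalues = fisher_enrichment_pvalues(
        background, anchored_nodes, set(candidate_edges)
    )
    cfg = ranker_config or RankerConfig()

    def score(candidate: str) -> float:
        p, _ = pvalues.get(candidate, (1.0, set()))
        return attribute_to_unit_score(p, "fisher_exact_p", cfg)

    ranked = sorted(candidate_edges, key=lambda c: (-score(c), c))
    kept: Set[str] = set()
    kept_edges: Set[str] = set()
    for candidate in ranked:
        eids = candidate_edges[candidate]
        if len(kept_edges | eids) > threshold:
            break
        kept.add(candidate)
        kept_edges |= eids

    dropped_nodes = set(candidate_edges) - kept
    dropped_edges = bound_edges - kept_edges
    state.qedge_bindings[qedge_key] = kept_edges
    state.qnode_bindings[growing_qnode_key] = set(
        state.qnode_bindings.get(growing_qnode_key, set())
    ) - dropped_nodes
    for eid in dropped_edges:
        kg.remove_edge(eid)
    _propagate_removals(state)
    state.info(
        f"pruned qedge {qedge_key!r} to threshold {threshold}: removed "
        f"{len(dropped_nodes)} candidate nodes and {len(dropped_edges)} edges"
    )
    return state


def _propagate_removals(state: ReasoningState) -> None:
    """Drop nodes that lost all support for their query node, plus dependent
    edges, until a fixpoint is reached."""
    kg = state.answer_kg
    pinned = set()
    for qnode in state.query_graph.nodes.values():
        if qnode.ids:
            pinned |= set(qnode.ids)
    changed = True
    while changed:
        changed = False
        # edges must connect currently-bound nodes
        for qedge_key, eids in list(state.qedge_bindings.items()):
            qedge = state.query_graph.edges.get(qedge_key)
            if qedge is None:  # virtual qedge keys are not constrained here
                continue
            allowed = state.qnode_bindings.get(qedge.subject_key, set()) | state.qnode_bindings.get(
                qedge.object_key, set()
            )
            for eid in list(eids):
                edge = kg.edges.get(eid)
                if edge is None or edge.subject not in kg.nodes or edge.object not in kg.nodes:
                    eids.discard(eid)
                    changed = True
                    continue
                if edge.subject not in allowed or edge.object not in allowed:
                    eids.discard(eid)
                    kg.remove_edge(eid)
                    changed = True
        # bound nodes must retain support from every adjacent fulfilled qedge
        for qnode_key, nids in list(state.qnode_bindings.items()):
            for qedge in state.query_graph.edges_at(qnode_key):
                if qedge.key not in state.qedge_bindings:
                    continue
                supported = set()
                for eid in state.qedge_bindings[qedge.key]:
                    edge = kg.edges.get(eid)
                    if edge is not None:
                        supported.add(edge.subject)
                        supported.add(edge.object)
                for nid in list(nids):
                    if nid not in supported:
                        nids.discard(nid)
                        changed = True
        # unbound, unpinned nodes leave the graph with their edges
        bound_everywhere = set().union(*state.qnode_bindings.values()) if state.qnode_bindings else set()
        for nid in list(kg.nodes):
            if nid not in bound_everywhere and nid not in pinned:
                kg.remove_node(nid)
                changed = True


def expand(
    state: ReasoningState,
    providers: Sequence[KnowledgeProvider],
    hierarchy: OntologyHierarchy,
    syn: Optional[Synonymizer],
    config: EngineConfig,
) -> ReasoningState:
    """Fulfill every query edge breadth-first and build the answer KG."""
    qg = state.query_graph
    if not qg.edges:
        raise ValueError("cannot expand: query graph has no edges")
    qg.validate()
    if not any(n.is_pinned for n in qg.nodes.values()):
        raise ValueError("cannot expand: query graph has no pinned node")

    pinned_sets: Dict[str, Set[str]] = {}
    for key, qnode in qg.nodes.items():
        if qnode.is_pinned:
            pinned_sets[key] = _expand_pinned_ids(qnode.ids or [], syn)

    background = merge_graphs(
        [p.graph for p in providers if hasattr(p, "graph")]
    )
    if syn is not None:
        background = canonicalize_graph(background, syn)

    fulfilled: Set[str] = set()
    while len(fulfilled) < len(qg.edges):
        qedge_key = _qedge_order(qg, fulfilled, state)[0]
        qedge = qg.edges[qedge_key]
        selected = select_providers(qedge, qg, providers, hierarchy)
        if not selected:
            state.warning(f"qedge {qedge_key!r}: no provider can fulfill it")
            fulfilled.add(qedge_key)
            continue

        def side_request(qnode_key: str) -> Tuple[Optional[frozenset], frozenset]:
            qnode = qg.nodes[qnode_key]
            if qnode.is_pinned:
                return frozenset(pinned_sets[qnode_key]), frozenset()
            bound = state.qnode_bindings.get(qnode_key)
            if bound:
                return frozenset(bound), frozenset()
            return None, frozenset(qnode.categories or [])

        subj_ids, subj_cats = side_request(qedge.subject_key)
        obj_ids, obj_cats = side_request(qedge.object_key)
        request = LookupRequest(
            subject_ids=subj_ids,
            object_ids=obj_ids,
            subject_categories=subj_cats,
            object_categories=obj_cats,
            predicates=frozenset(qedge.predicates or []),
        )

        fragments: List[KnowledgeGraph] = []
        for provider in sorted(selected, key=lambda p: p.name):
            frag = _lookup_with_timeout(provider, request, config.kp_timeout)
            if frag is None:
                state.warning(
                    f"provider {provider.name!r} exceeded the {config.kp_timeout}s "
                    f"budget for qedge {qedge_key!r}; abandoned"
                )
                continue
            if syn is not None:
                frag = canonicalize_graph(frag, syn)
            fragments.append(frag)
            state.info(
                f"qedge {qedge_key!r}: provider {provider.name!r} returned "
                f"{len(frag.edges)} edges"
            )

        merged = merge_graphs([state.answer_kg] + fragments)
        state.answer_kg = merged

        # record which merged edges fulfill this qedge, and in which roles
        new_edge_ids: Set[str] = set()
        subj_bound: Set[str] = set()
        obj_bound: Set[str] = set()
        for eid, edge in merged.edges.items():
            if edge.is_virtual:
                continue
            for role_s, role_o in _edge_orientations(
                edge, qedge, qg, merged, state, hierarchy, pinned_sets
            ):
                new_edge_ids.add(eid)
                if role_s == qedge.subject_key:
                    subj_bound.add(edge.subject)
                    obj_bound.add(edge.object)
                else:
                    obj_bound.add(edge.subject)
                    subj_bound.add(edge.object)
        state.qedge_bindings[qedge_key] = new_edge_ids
        # a side already bound by earlier qedges narrows to the intersection
        # with this qedge's support; a fresh side takes the support outright
        for qnode_key, supported in (
            (qedge.subject_key, subj_bound),
            (qedge.object_key, obj_bound),
        ):
            prior = state.qnode_bindings.get(qnode_key)
            if prior:
                state.qnode_bindings[qnode_key] = prior & supported
            else:
                state.qnode_bindings[qnode_key] = set(supported)

        if not new_edge_ids:
            state.warning(f"qedge {qedge_key!r}: zero surviving triples")
            fulfilled.add(qedge_key)
            _propagate_removals(state)
            continue

        threshold = default_prune_threshold(qedge, qg, hierarchy, config)
        growing = None
        if not qg.nodes[qedge.object_key].is_pinned:
            growing = qedge.object_key
        if not qg.nodes[qedge.subject_key].is_pinned and growing is None:
            growing = qedge.subject_key
        prune_qedge_answers(
            state,
            qedge_key,
            threshold,
            background,
            growing_qnode_key=growing or qedge.object_key,
        )
        fulfilled.add(qedge_key)
        _propagate_removals(state)

    state.info(
        f"expansion complete: {len(state.answer_kg.nodes)} nodes, "
        f"{len(state.answer_kg.edges)} edges"
    )
    return state
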