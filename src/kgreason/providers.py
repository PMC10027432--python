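"""Local knowledge-provider contract and engine configuration.

A knowledge provider answers one-hop requests: given pinned ids on one side
(or both), allowed categories for the unpinned side and allowed predicates,
it returns the matching knowledge-graph fragment.  Providers also publish
meta-triples — (subject category, predicate, object category) combinations —
that truthfully cover everything their lookup can return, which the expander
uses to route query edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Sequence, Set

from .graph import KnowledgeEdge, KnowledgeGraph, MetaTriple
from .hierarchy import CATEGORY, OntologyHierarchy, term_matches


@dataclass(frozen=True)
class LookupRequest:
    """One-hop request. ``subject_ids``/``object_ids`` pin a side to specific
    concepts (None = unpinned); categories/predicates are disjunctive
    constraint sets (empty = unconstrained)."""

    subject_ids: Optional[FrozenSet[str]] = None
    object_ids: Optional[FrozenSet[str]] = None
    subject_categories: FrozenSet[str] = frozenset()
    object_categories: FrozenSet[str] = frozenset()
    predicates: FrozenSet[str] = frozenset()


class KnowledgeProvider:
    """Abstract provider contract."""

    name: str = "abstract"

    def meta_triples(self) -> Sequence[MetaTriple]:
        raise NotImplementedError

    def lookup(self, request: LookupRequest) -> KnowledgeGraph:
        raise NotImplementedError


class GraphProvider(KnowledgeProvider):
    """A provider backed by an in-memory knowledge graph.

    ``lookup`` scans the backing graph for edges satisfying the request after
    hierarchy expansion of category and predicate constraints, in either
    stated orientation of the edge relative to the request.
    """

    def __init__(
        self,
        name: str,
        graph: KnowledgeGraph,
        hierarchy: OntologyHierarchy,
        meta: Optional[Sequence[MetaTriple]] = None,
    ):
        self.name = name
        self.graph = graph
        self.hierarchy = hierarchy
        self._meta = list(meta) if meta is not None else self._derive_meta()

    def _derive_meta(self) -> List[MetaTriple]:
        seen: Set[MetaTriple] = set()
        for e in self.graph.edges.values():
            for sc in self.graph.nodes[e.subject].categories:
                for oc in self.graph.nodes[e.object].categories:
                    seen.add(MetaTriple(sc, e.predicate, oc))
        return sorted(seen, key=lambda m: (m.subject_category, m.predicate, m.object_category))

    def meta_triples(self) -> Sequence[MetaTriple]:
        return self._meta

    def _node_ok(
        self,
        node_id: str,
        pinned: Optional[FrozenSet[str]],
        categories: FrozenSet[str],
    ) -> bool:
        if pinned is not None:
            return node_id in pinned
        node = self.graph.nodes[node_id]
        return any(term_matches(self.hierarchy, c, categories) for c in node.categories)

    def _edge_ok(self, edge: KnowledgeEdge, request: LookupRequest) -> bool:
        if not term_matches(self.hierarchy, edge.predicate, request.predicates):
            return False
        # either orientation may satisfy the request; direction semantics are
        # enforced downstream by resultify, not at retrieval time
        forward = self._node_ok(
            edge.subject, request.subject_ids, request.subject_categories
        ) and self._node_ok(edge.object, request.object_ids, request.object_categories)
        reverse = self._node_ok(
            edge.object, request.subject_ids, request.subject_categories
        ) and self._node_ok(edge.subject, request.object_ids, request.object_categories)
        return forward or reverse

    def lookup(self, request: LookupRequest) -> KnowledgeGraph:
        frag = KnowledgeGraph()
        for edge in self.graph.edges.values():
            if self._edge_ok(edge, request):
                for nid in (edge.subject, edge.object):
                    if nid not in frag.nodes:
                        src = self.graph.nodes[nid]
                        frag.add_node(
                            type(src)(
                                src.id, src.name, set(src.categories), list(src.attributes)
                            )
                        )
                from dataclasses import replace

                frag.add_edge(replace(edge, attributes=list(edge.attributes)))
        return frag


@dataclass
class EngineConfig:
    """Execution knobs threaded through the engine.

    ``prune_threshold`` overrides the adaptive per-query-edge default when
    set. ``kp_timeout`` is the per-provider wall-clock budget in seconds for
    one query edge. ``prevalent_categories`` marks categories so common in
    providers that query edges touching them get a tighter prune threshold;
    when None it defaults to the depth-1 categories of the loaded hierarchy.
    """

    prune_threshold: Optional[int] = None
    kp_timeout: float = 30.0
    prevalent_categories: Optional[Set[str]] = None
    seed: int = 0
    base_edge_score: float = 0.5

    def __post_init__(self):
        if self.prune_threshold is not None and self.prune_threshold < 1:
            raise ValueError("prune_threshold must be positive")
        if self.kp_timeout <= 0:
            raise ValueError("kp_timeout must be positive")

    def effective_prevalent(self, hierarchy: OntologyHierarchy) -> Set[str]:
        if self.prevalent_categories is not None:
            return set(self.prevalent_categories)
        if CATEGORY in hierarchy.roots:
            return set(hierarchy.depth1_terms(CATEGORY))
        return set()
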