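"""Enumerate every subgraph of the answer KG that fulfills the query graph.

A node-binding map (query node key -> KG node id) fulfills the query graph
when (i) each bound node's categories satisfy its query node's category
constraint under hierarchy expansion, (ii) pinned query nodes bind only their
listed ids, and (iii) every query edge is witnessed by at least one KG edge
between the bound endpoints whose predicate satisfies the constraint —
oriented subject-to-object when edge direction is enforced, either way when
it is ignored.  One result corresponds to one distinct node-binding map; all
qualifying KG edges (including parallel ones) are grouped under the query
edge key, and overlay-created virtual edges between bound nodes ride along
under their own virtual keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .graph import KnowledgeGraph
from .hierarchy import OntologyHierarchy, term_matches
from .querygraph import QueryGraph
from .state import ReasoningState


@dataclass
class Result:
    node_bindings: Dict[str, str]
    edge_bindings: Dict[str, Set[str]] = field(default_factory=dict)
    score: Optional[float] = None

    def signature(self) -> Tuple[Tuple[str, str], ...]:
        return tuple(sorted(self.node_bindings.items()))


def _node_ok(
    kg: KnowledgeGraph,
    qg: QueryGraph,
    qnode_key: str,
    node_id: str,
    hierarchy: OntologyHierarchy,
) -> bool:
    qnode = qg.nodes[qnode_key]
    node = kg.nodes.get(node_id)
    if node is None:
        return False
    if qnode.is_pinned and node_id not in (qnode.ids or []):
        return False
    if qnode.categories:
        if not any(term_matches(hierarchy, c, qnode.categories) for c in node.categories):
            return False
    return True


def _matching_edges(
    kg: KnowledgeGraph,
    qg: QueryGraph,
    qedge_key: str,
    subject_id: str,
    object_id: str,
    hierarchy: OntologyHierarchy,
    ignore_edge_direction: bool,
) -> Set[str]:
    qedge = qg.edges[qedge_key]
    out: Set[str] = set()
    for eid, edge in kg.edges.items():
        if edge.is_virtual:
            continue
        if not term_matches(hierarchy, edge.predicate, qedge.predicates or []):
            continue
        forward = edge.subject == subject_id and edge.object == object_id
        reverse = edge.subject == object_id and edge.object == subject_id
        if forward or (ignore_edge_direction and reverse):
            out.add(eid)
    return out


def binding_fulfills(
    qg: QueryGraph,
    kg: KnowledgeGraph,
    node_bindings: Dict[str, str],
    hierarchy: OntologyHierarchy,
    ignore_edge_direction: bool = True,
) -> bool:
    """Independent checker: does this complete node-binding map fulfill the
    query graph?  Usable as an oracle against the enumerator."""
    for key in qg.nodes:
        if key not in node_bindings:
            raise ValueError(f"binding missing query node {key!r}")
        node_id = node_bindings[key]
        if node_id not in kg.nodes:
            raise ValueError(f"binding references unknown KG node {node_id!r}")
        if not _node_ok(kg, qg, key, node_id, hierarchy):
            return False
    for qedge_key, qedge in qg.edges.items():
        edges = _matching_edges(
            kg,
            qg,
            qedge_key,
            node_bindings[qedge.subject_key],
            node_bindings[qedge.object_key],
            hierarchy,
            ignore_edge_direction,
        )
        if not edges:
            return False
    return True


def _attach_virtual_edges(result: Result, kg: KnowledgeGraph) -> None:
    bound = set(result.node_bindings.values())
    for eid, edge in kg.edges.items():
        if not edge.is_virtual or edge.qedge_key is None:
            continue
        if edge.subject in bound and edge.object in bound:
            result.edge_bindings.setdefault(edge.qedge_key, set()).add(eid)


def enumerate_results(
    qg: QueryGraph,
    kg: KnowledgeGraph,
    hierarchy: OntologyHierarchy,
    ignore_edge_direction: bool = True,
    strict_injective: bool = False,
) -> List[Result]:
    """Backtracking enumeration of all fulfilling node-binding maps.

    Query nodes are assigned in ascending candidate-set order; each partial
    assignment is checked against every query edge whose endpoints are both
    assigned (forward constraint propagation).  With ``strict_injective`` two
    query nodes may not bind the same KG node.
    """
    qg.validate()
    candidates: Dict[str, List[str]] = {}
    for key in qg.nodes:
        candidates[key] = sorted(
            nid for nid in kg.nodes if _node_ok(kg, qg, key, nid, hierarchy)
        )
        if not candidates[key]:
            return []
    order = sorted(qg.nodes, key=lambda k: (len(candidates[k]), k))

    results: List[Result] = []
    binding: Dict[str, str] = {}

    def consistent(key: str) -> bool:
        for qedge in qg.edges_at(key):
            if qedge.subject_key in binding and qedge.object_key in binding:
                if not _matching_edges(
                    kg,
                    qg,
                    qedge.key,
                    binding[qedge.subject_key],
                    binding[qedge.object_key],
                    hierarchy,
                    ignore_edge_direction,
                ):
                    return False
        return True

    def backtrack(depth: int) -> None:
        if depth == len(order):
            result = Result(node_bindings=dict(binding))
            for qedge_key, qedge in qg.edges.items():
                result.edge_bindings[qedge_key] = _matching_edges(
                    kg,
                    qg,
                    qedge_key,
                    binding[qedge.subject_key],
                    binding[qedge.object_key],
                    hierarchy,
                    ignore_edge_direction,
                )
            _attach_virtual_edges(result, kg)
            results.append(result)
            return
        key = order[depth]
        for nid in candidates[key]:
            if strict_injective and nid in binding.values():
                continue
            binding[key] = nid
            if consistent(key):
                backtrack(depth + 1)
            del binding[key]

    backtrack(0)
    results.sort(key=lambda r: r.signature())
    return results


def resultify(
    state: ReasoningState,
    hierarchy: OntologyHierarchy,
    ignore_edge_direction: bool = True,
    strict_injective: bool = False,
) -> ReasoningState:
    """Populate ``state.results`` with every fulfilling subgraph."""
    if not state.answer_kg.nodes:
        raise ValueError("cannot resultify: answer KG is empty")
    state.results = enumerate_results(
        state.query_graph,
        state.answer_kg,
        hierarchy,
        ignore_edge_direction=ignore_edge_direction,
        strict_injective=strict_injective,
    )
    state.ranked = False
    state.info(f"resultify: {len(state.results)} results")
    return state
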