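"""Core knowledge-graph data model.

A knowledge graph is a labeled multigraph: nodes are concepts identified by
CURIEs (``MONDO:0019391``) carrying one or more category terms; edges are
subject–predicate–object triples with provenance and arbitrary attributes.
Parallel edges (same endpoints, different predicate or source) are first
class citizens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

logger = logging.getLogger(__name__)

AttrValue = Union[int, float, str, Sequence[str]]


@dataclass(frozen=True)
class Attribute:
    """A named annotation on a node or edge.

    ``value`` is a number, a string, or a sequence of strings (e.g. a list of
    publication identifiers). ``source`` names the operation or provider that
    produced the annotation.
    """

    name: str
    value: AttrValue
    source: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValueError("attribute name must be nonempty")
        if isinstance(self.value, float):
            import math

            if not math.isfinite(self.value):
                raise ValueError(f"attribute {self.name!r} has non-finite value")


@dataclass
class ConceptNode:
    id: str
    name: str
    categories: Set[str]
    attributes: List[Attribute] = field(default_factory=list)

    def __post_init__(self):
        self.categories = set(self.categories)
        if not self.categories:
            raise ValueError(f"node {self.id} must have at least one category")


@dataclass
class KnowledgeEdge:
    id: str
    subject: str
    object: str
    predicate: str
    primary_source: str = ""
    is_virtual: bool = False
    qedge_key: Optional[str] = None  # set only on virtual edges
    attributes: List[Attribute] = field(default_factory=list)

    @property
    def dedup_key(self) -> Tuple[str, str, str, str]:
        return (self.subject, self.object, self.predicate, self.primary_source)

    def get_attribute(self, name: str) -> Optional[Attribute]:
        for a in self.attributes:
            if a.name == name:
                return a
        return None


@dataclass(frozen=True)
class MetaTriple:
    """A (subject category, predicate, object category) capability claim."""

    subject_category: str
    predicate: str
    object_category: str


class KnowledgeGraph:
    """A labeled multigraph of concept nodes and attributed edges."""

    def __init__(
        self,
        nodes: Iterable[ConceptNode] = (),
        edges: Iterable[KnowledgeEdge] = (),
    ):
        self.nodes: Dict[str, ConceptNode] = {}
        self.edges: Dict[str, KnowledgeEdge] = {}
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    def add_node(self, node: ConceptNode) -> None:
        self.nodes[node.id] = node

    def add_edge(self, edge: KnowledgeEdge) -> None:
        if edge.subject not in self.nodes:
            raise ValueError(f"edge {edge.id}: unknown subject {edge.subject}")
        if edge.object not in self.nodes:
            raise ValueError(f"edge {edge.id}: unknown object {edge.object}")
        self.edges[edge.id] = edge

    def remove_edge(self, edge_id: str) -> None:
        self.edges.pop(edge_id, None)

    def remove_node(self, node_id: str) -> None:
        """Remove a node and every edge touching it."""
        self.nodes.pop(node_id, None)
        for eid in [
            eid
            for eid, e in self.edges.items()
            if e.subject == node_id or e.object == node_id
        ]:
            del self.edges[eid]

    def edges_between(self, a: str, b: str) -> List[KnowledgeEdge]:
        """All edges with endpoints {a, b}, either orientation."""
        return [
            e
            for e in self.edges.values()
            if {e.subject, e.object} == {a, b}
            or (a == b and e.subject == a and e.object == a)
        ]

    def neighbors(self, node_id: str) -> Set[str]:
        """Distinct adjacent node ids, direction ignored, self excluded."""
        out: Set[str] = set()
        for e in self.edges.values():
            if e.subject == node_id and e.object != node_id:
                out.add(e.object)
            elif e.object == node_id and e.subject != node_id:
                out.add(e.subject)
        return out

    def copy(self) -> "KnowledgeGraph":
        g = KnowledgeGraph()
        for n in self.nodes.values():
            g.add_node(
                ConceptNode(n.id, n.name, set(n.categories), list(n.attributes))
            )
        for e in self.edges.values():
            g.add_edge(replace(e, attributes=list(e.attributes)))
        return g

    def __len__(self) -> int:
        return len(self.nodes)

    def __repr__(self) -> str:
        return f"KnowledgeGraph({len(self.nodes)} nodes, {len(self.edges)} edges)"

    def same_content(self, other: "KnowledgeGraph") -> bool:
        """Equality up to edge-id relabeling (node ids and triple identity)."""
        if set(self.nodes) != set(other.nodes):
            return False
        mine = sorted(e.dedup_key for e in self.edges.values())
        theirs = sorted(e.dedup_key for e in other.edges.values())
        return mine == theirs


def _merge_attributes(
    base: List[Attribute], extra: Iterable[Attribute]
) -> List[Attribute]:
    # first-writer-wins by attribute name; unseen names appended in order
    seen = {a.name for a in base}
    out = list(base)
    for a in extra:
        if a.name not in seen:
            out.append(a)
            seen.add(a.name)
    return out


def merge_graphs(graphs: Sequence[KnowledgeGraph]) -> KnowledgeGraph:
    """Union of graphs: nodes keyed by id, edges deduplicated by triple+source.

    Two edges are duplicates iff they agree on (subject, object, predicate,
    primary_source); the same triple asserted by two sources is kept twice.
    Node attribute conflicts resolve first-writer-wins; a node-name conflict
    keeps the first name and logs a warning.
    """
    merged = KnowledgeGraph()
    seen_edges: Dict[Tuple[str, str, str, str], str] = {}
    for g in graphs:
        for node in g.nodes.values():
            existing = merged.nodes.get(node.id)
            if existing is None:
                merged.add_node(
                    ConceptNode(
                        node.id, node.name, set(node.categories), list(node.attributes)
                    )
                )
            else:
                if existing.name != node.name:
                    logger.warning(
                        "node %s: conflicting names %r / %r; keeping first",
                        node.id,
                        existing.name,
                        node.name,
                    )
                existing.categories |= node.categories
                existing.attributes = _merge_attributes(
                    existing.attributes, node.attributes
                )
        for edge in g.edges.values():
            key = edge.dedup_key
            if key in seen_edges:
                kept = merged.edges[seen_edges[key]]
                kept.attributes = _merge_attributes(kept.attributes, edge.attributes)
                continue
            eid = edge.id
            if eid in merged.edges:
                eid = f"{eid}#{len(merged.edges)}"
            merged.add_edge(replace(edge, id=eid, attributes=list(edge.attributes)))
            seen_edges[key] = eid
    return merged
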