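"""Query graphs: connected constraint patterns that answers must instantiate.

A query node is optionally *pinned* to specific concept ids and optionally
constrained to category terms; a query edge optionally constrains the
predicate.  Query graphs may contain cycles and parallel edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence


@dataclass
class QueryNode:
    key: str
    ids: Optional[List[str]] = None
    categories: Optional[List[str]] = None

    @property
    def is_pinned(self) -> bool:
        return bool(self.ids)


@dataclass
class QueryEdge:
    key: str
    subject_key: str
    object_key: str
    predicates: Optional[List[str]] = None


@dataclass
class QueryGraph:
    nodes: Dict[str, QueryNode] = field(default_factory=dict)
    edges: Dict[str, QueryEdge] = field(default_factory=dict)

    def add_node(self, node: QueryNode) -> None:
        if node.key in self.nodes:
            raise ValueError(f"duplicate query node key {node.key!r}")
        self.nodes[node.key] = node

    def add_edge(self, edge: QueryEdge) -> None:
        if edge.key in self.edges:
            raise ValueError(f"duplicate query edge key {edge.key!r}")
        for k in (edge.subject_key, edge.object_key):
            if k not in self.nodes:
                raise ValueError(f"query edge {edge.key!r}: unknown node key {k!r}")
        self.edges[edge.key] = edge

    def pinned_ids(self) -> List[str]:
        out: List[str] = []
        for n in self.nodes.values():
            if n.ids:
                out.extend(n.ids)
        return out

    def qnode_degree(self, key: str) -> int:
        return sum(
            (e.subject_key == key) + (e.object_key == key)
            for e in self.edges.values()
        )

    def edges_at(self, key: str) -> List[QueryEdge]:
        return [
            e
            for e in self.edges.values()
            if e.subject_key == key or e.object_key == key
        ]

    def is_connected(self) -> bool:
        """Connectivity of the underlying undirected graph (isolated single
        node counts as connected)."""
        if not self.nodes:
            return False
        if not self.edges:
            return len(self.nodes) == 1
        adj: Dict[str, set] = {k: set() for k in self.nodes}
        for e in self.edges.values():
            adj[e.subject_key].add(e.object_key)
            adj[e.object_key].add(e.subject_key)
        start = next(iter(self.nodes))
        seen = {start}
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.nodes)

    def validate(self) -> None:
        if not self.is_connected():
            raise ValueError("query graph must be connected")


def query_graph_from_dict(data: dict) -> QueryGraph:
    """Build a QueryGraph from the JSON message layout
    ``{"nodes": {key: {...}}, "edges": {key: {...}}}``."""
    qg = QueryGraph()
    nodes = data.get("nodes", {})
    edges = data.get("edges", {})
    for key in sorted(nodes):
        spec = nodes[key]
        qg.add_node(
            QueryNode(
                key=key,
                ids=list(spec["ids"]) if spec.get("ids") else None,
                categories=(
                    list(spec["categories"]) if spec.get("categories") else None
                ),
            )
        )
    for key in sorted(edges):
        spec = edges[key]
        for req in ("subject", "object"):
            if req not in spec:
                raise ValueError(
                    f"schema violation at message.query_graph.edges.{key}.{req}:"
                    " missing"
                )
        qg.add_edge(
            QueryEdge(
                key=key,
                subject_key=spec["subject"],
                object_key=spec["object"],
                predicates=(
                    list(spec["predicates"]) if spec.get("predicates") else None
                ),
            )
        )
    return qg


def query_graph_to_dict(qg: QueryGraph) -> dict:
    nodes = {}
    for key, n in qg.nodes.items():
        spec: dict = {}
        if n.ids:
            spec["ids"] = list(n.ids)
        if n.categories:
            spec["categories"] = list(n.categories)
        nodes[key] = spec
    edges = {}
    for key, e in qg.edges.items():
        spec = {"subject": e.subject_key, "object": e.object_key}
        if e.predicates:
            spec["predicates"] = list(e.predicates)
        edges[key] = spec
    return {"nodes": nodes, "edges": edges}
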