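"""Answer-KG filtering and result-list sorting/limiting.

Multi-hop queries can build large answer graphs; filtering removes nodes or
edges whose overlay-supplied numeric attributes fall on the wrong side of a
user threshold, and sorts or truncates the result list.  Targets lacking the
named attribute are retained: absence of evidence is not evidence against.
"""

from __future__ import annotations

from typing import Set

from .state import ReasoningState

_DIRECTIONS = ("above", "below")
_SORT_KEYS = ("score", "edge_count", "node_count")


def _numeric_attribute(item, name: str):
    for attr in item.attributes:
        if attr.name == name and isinstance(attr.value, (int, float)):
            return float(attr.value)
    return None


def filter_kg(
    state: ReasoningState,
    target: str,
    attribute_name: str,
    direction: str,
    threshold: float,
    remove_orphans: bool = False,
) -> ReasoningState:
    """Remove nodes or edges whose numeric attribute is strictly above/below
    the threshold.  Pinned nodes are never removed; with ``remove_orphans``,
    unpinned nodes left edgeless are dropped too.  Any previously computed
    results are invalidated (re-run resultify)."""
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    if target not in ("edge", "node"):
        raise ValueError(f"target must be 'edge' or 'node', got {target!r}")
    if not attribute_name:
        raise ValueError("attribute_name must be nonempty")

    kg = state.answer_kg
    pinned: Set[str] = set(state.query_graph.pinned_ids())

    def offends(value: float) -> bool:
        return value > threshold if direction == "above" else value < threshold

    removed = 0
    if target == "edge":
        for eid in list(kg.edges):
            v = _numeric_attribute(kg.edges[eid], attribute_name)
            if v is not None and offends(v):
                kg.remove_edge(eid)
                for bound in state.qedge_bindings.values():
                    bound.discard(eid)
                removed += 1
    else:
        for nid in list(kg.nodes):
            if nid in pinned:
                continue
            v = _numeric_attribute(kg.nodes[nid], attribute_name)
            if v is not None and offends(v):
                kg.remove_node(nid)
                for bound in state.qnode_bindings.values():
                    bound.discard(nid)
                removed += 1

    orphans = 0
    if remove_orphans:
        with_edges = set()
        for e in kg.edges.values():
            with_edges.add(e.subject)
            with_edges.add(e.object)
        for nid in list(kg.nodes):
            if nid not in with_edges and nid not in pinned:
                kg.remove_node(nid)
                for bound in state.qnode_bindings.values():
                    bound.discard(nid)
                orphans += 1

    state.info(
        f"filter_kg: removed {removed} {target}s"
        + (f" and {orphans} orphaned nodes" if remove_orphans else "")
    )
    if state.results and removed + orphans > 0:
        state.results = []
        state.warning("filter_kg invalidated existing results; re-run resultify")
    return state


def filter_results(
    state: ReasoningState,
    sort_by: str = "score",
    ascending: bool = False,
    limit: int = 0,
) -> ReasoningState:
    """Stable-sort results by score, edge/node count, or a named edge
    attribute (``attribute:<name>``, taking the maximum over bound edges;
    results lacking it sort last), then truncate to ``limit`` (0 = keep all).
    """
    if not state.results:
        state.warning("filter_results: no results present")
        return state
    if limit < 0:
        raise ValueError("limit must be non-negative")

    if sort_by == "score":
        def key(r):
            return r.score if r.score is not None else float("-inf")
        missing_last = False
    elif sort_by == "edge_count":
        def key(r):
            return sum(len(v) for v in r.edge_bindings.values())
        missing_last = False
    elif sort_by == "node_count":
        def key(r):
            return len(r.node_bindings)
        missing_last = False
    elif sort_by.startswith("attribute:"):
        attr_name = sort_by.split(":", 1)[1]

        def key(r):
            values = []
            for eids in r.edge_bindings.values():
                for eid in eids:
                    edge = state.answer_kg.edges.get(eid)
                    if edge is None:
                        continue
                    v = _numeric_attribute(edge, attr_name)
                    if v is not None:
                        values.append(v)
            return max(values) if values else None
        missing_last = True
    else:
        raise ValueError(
            f"unknown sort key {sort_by!r}; expected one of {_SORT_KEYS} or 'attribute:<name>'"
        )

    if missing_last:
        # missing attribute sorts last regardless of direction
        present = [r for r in state.results if key(r) is not None]
        absent = [r for r in state.results if key(r) is None]
        present.sort(key=key, reverse=not ascending)
        ordered = present + absent
    else:
        ordered = sorted(state.results, key=key, reverse=not ascending)

    if limit:
        ordered = ordered[:limit]
    state.results = ordered
    state.info(f"filter_results: {len(ordered)} results retained")
    return state
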