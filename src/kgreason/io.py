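"""File I/O: TSV graph tables, hierarchy files, provider bundles,
co-occurrence indexes, JSON query messages and responses.

Formats are deliberately plain: tab-separated tables for graphs and
hierarchies, JSON for messages.  Node table columns: ``id, name, categories``
(pipe-separated) and optional ``attributes`` (JSON object).  Edge table
columns: ``id, subject, object, predicate, primary_source`` and optional
``attributes``.  Hierarchy files are two-column ``child<TAB>parent`` tables
with roots declared by a parent of ``-``.
"""

from __future__ import annotations

import json
import math
import os
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from .graph import Attribute, ConceptNode, KnowledgeEdge, KnowledgeGraph
from .hierarchy import CATEGORY, PREDICATE, OntologyHierarchy
from .overlay import CooccurrenceIndex
from .providers import GraphProvider
from .graph import MetaTriple
from .querygraph import QueryGraph, query_graph_from_dict, query_graph_to_dict
from .state import ReasoningState
from .synonymizer import EquivalenceAssertion

PathLike = Union[str, os.PathLike]


class TableFormatError(ValueError):
    pass


def _read_tsv(path: PathLike, expected: Sequence[str]) -> List[Dict[str, str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in expected if c not in header]
        if missing:
            raise TableFormatError(f"{path}: missing column(s) {missing}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(expected):
                raise TableFormatError(
                    f"{path}:{lineno}: expected >= {len(expected)} fields, got {len(fields)}"
                )
            rows.append(
                {col: (fields[i] if i < len(fields) else "") for i, col in enumerate(header)}
            )
    return rows


def _parse_attributes(raw: str, where: str) -> List[Attribute]:
    if not raw:
        return []
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise TableFormatError(f"{where}: bad attributes JSON: {exc}") from exc
    return [Attribute(name=k, value=v) for k, v in data.items()]


def read_hierarchy(
    category_path: PathLike, predicate_path: PathLike
) -> OntologyHierarchy:
    """Load the category and predicate hierarchies from child–parent tables."""
    h = OntologyHierarchy()
    for namespace, path in ((CATEGORY, category_path), (PREDICATE, predicate_path)):
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise TableFormatError(
                        f"{path}:{lineno}: expected child<TAB>parent"
                    )
                child, parent = parts
                if parent == "-":
                    h.add_term(namespace, child)
                    h.roots[namespace] = child
                else:
                    h.add_term(namespace, child, [parent])
    h.validate()
    return h


def write_hierarchy(
    hierarchy: OntologyHierarchy, category_path: PathLike, predicate_path: PathLike
) -> None:
    for namespace, path in (
        (CATEGORY, category_path),
        (PREDICATE, predicate_path),
    ):
        with open(path, "w", encoding="utf-8") as fh:
            for term in sorted(hierarchy.parents[namespace]):
                parents = sorted(hierarchy.parents[namespace][term])
                if not parents:
                    fh.write(f"{term}\t-\n")
                for p in parents:
                    fh.write(f"{term}\t{p}\n")


def read_kg_tables(
    node_path: PathLike,
    edge_path: PathLike,
    hierarchy: Optional[OntologyHierarchy] = None,
) -> KnowledgeGraph:
    """Load a knowledge graph from node and edge TSV tables, validating
    invariants (dangling endpoints, unknown category/predicate terms)."""
    kg = KnowledgeGraph()
    for row in _read_tsv(node_path, ("id", "name", "categories")):
        cats = set(filter(None, row["categories"].split("|")))
        if hierarchy is not None:
            for c in cats:
                if not hierarchy.has_term(CATEGORY, c):
                    raise TableFormatError(
                        f"{node_path}: node {row['id']}: unknown category {c!r}"
                    )
        kg.add_node(
            ConceptNode(
                id=row["id"],
                name=row["name"],
                categories=cats,
                attributes=_parse_attributes(
                    row.get("attributes", ""), f"node {row['id']}"
                ),
            )
        )
    for row in _read_tsv(
        edge_path, ("id", "subject", "object", "predicate", "primary_source")
    ):
        for endpoint in ("subject", "object"):
            if row[endpoint] not in kg.nodes:
                raise TableFormatError(
                    f"{edge_path}: edge {row['id']}: dangling {endpoint} "
                    f"{row[endpoint]!r}"
                )
        if hierarchy is not None and not hierarchy.has_term(
            PREDICATE, row["predicate"]
        ):
            raise TableFormatError(
                f"{edge_path}: edge {row['id']}: unknown predicate "
                f"{row['predicate']!r}"
            )
        kg.add_edge(
            KnowledgeEdge(
                id=row["id"],
                subject=row["subject"],
                object=row["object"],
                predicate=row["predicate"],
                primary_source=row["primary_source"],
                attributes=_parse_attributes(
                    row.get("attributes", ""), f"edge {row['id']}"
                ),
            )
        )
    return kg


def _attributes_json(attrs: Sequence[Attribute]) -> str:
    if not attrs:
        return ""
    return json.dumps(
        {a.name: (list(a.value) if isinstance(a.value, (list, tuple)) else a.value)
         for a in attrs},
        sort_keys=True,
    )


def write_kg_tables(
    kg: KnowledgeGraph, node_path: PathLike, edge_path: PathLike
) -> None:
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("id\tname\tcategories\tattributes\n")
        for nid in sorted(kg.nodes):
            n = kg.nodes[nid]
            fh.write(
                f"{n.id}\t{n.name}\t{'|'.join(sorted(n.categories))}\t"
                f"{_attributes_json(n.attributes)}\n"
            )
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("id\tsubject\tobject\tpredicate\tprimary_source\tattributes\n")
        for eid in sorted(kg.edges):
            e = kg.edges[eid]
            fh.write(
                f"{e.id}\t{e.subject}\t{e.object}\t{e.predicate}\t"
                f"{e.primary_source}\t{_attributes_json(e.attributes)}\n"
            )


def read_assertions(path: PathLike) -> List[EquivalenceAssertion]:
    return [
        EquivalenceAssertion(row["id_a"], row["id_b"], row["evidence"])
        for row in _read_tsv(path, ("id_a", "id_b", "evidence"))
    ]


def write_assertions(
    assertions: Sequence[EquivalenceAssertion], path: PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tevidence\n")
        for a in assertions:
            fh.write(f"{a.id_a}\t{a.id_b}\t{a.evidence}\n")


def read_cooccurrence_index(path: PathLike) -> CooccurrenceIndex:
    """Co-occurrence file: sectioned TSV with records
    ``term<TAB>NAME<TAB>COUNT``, ``pair<TAB>NAME1<TAB>NAME2<TAB>COUNT`` and a
    single ``total<TAB>N`` line."""
    index = CooccurrenceIndex()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            kind = parts[0]
            try:
                if kind == "term" and len(parts) == 3:
                    index.add_term(parts[1], int(parts[2]))
                elif kind == "pair" and len(parts) == 4:
                    index.add_pair(parts[1], parts[2], int(parts[3]))
                elif kind == "total" and len(parts) == 2:
                    index.total = int(parts[1])
                else:
                    raise ValueError("unrecognized record")
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
    index.validate()
    return index


def write_cooccurrence_index(index: CooccurrenceIndex, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"total\t{index.total}\n")
        for term in sorted(index.occurrence):
            fh.write(f"term\t{term}\t{index.occurrence[term]}\n")
        for key in sorted(index.pair, key=sorted):
            pair = sorted(key)
            t1, t2 = pair[0], pair[-1]
            fh.write(f"pair\t{t1}\t{t2}\t{index.pair[key]}\n")


def read_meta_triples(path: PathLike) -> List[MetaTriple]:
    return [
        MetaTriple(row["subject_category"], row["predicate"], row["object_category"])
        for row in _read_tsv(path, ("subject_category", "predicate", "object_category"))
    ]


def write_meta_triples(meta: Sequence[MetaTriple], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("subject_category\tpredicate\tobject_category\n")
        for m in meta:
            fh.write(f"{m.subject_category}\t{m.predicate}\t{m.object_category}\n")


def load_provider_bundle(
    directory: PathLike, hierarchy: OntologyHierarchy, name: Optional[str] = None
) -> GraphProvider:
    """Load a provider bundle directory (nodes.tsv, edges.tsv and optional
    meta_triples.tsv) as an in-memory provider."""
    d = Path(directory)
    kg = read_kg_tables(d / "nodes.tsv", d / "edges.tsv", hierarchy)
    meta_path = d / "meta_triples.tsv"
    meta = read_meta_triples(meta_path) if meta_path.exists() else None
    return GraphProvider(name or d.name, kg, hierarchy, meta)


def read_query_message(path: PathLike) -> QueryGraph:
    """Parse a JSON query message ``{"message": {"query_graph": {...}}}``."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    try:
        qg_data = data["message"]["query_graph"]
    except (KeyError, TypeError) as exc:
        raise ValueError("schema violation at message.query_graph: missing") from exc
    qg = query_graph_from_dict(qg_data)
    qg.validate()
    return qg


def _edge_to_dict(edge: KnowledgeEdge) -> dict:
    out = {
        "subject": edge.subject,
        "object": edge.object,
        "predicate": edge.predicate,
        "primary_source": edge.primary_source,
        "attributes": [
            {
                "name": a.name,
                "value": (
                    list(a.value) if isinstance(a.value, (list, tuple)) else a.value
                ),
                "source": a.source,
            }
            for a in edge.attributes
        ],
    }
    if edge.is_virtual:
        out["is_virtual"] = True
        out["qedge_key"] = edge.qedge_key
    return out


def response_to_dict(state: ReasoningState) -> dict:
    kg = state.answer_kg
    return {
        "message": {
            "query_graph": query_graph_to_dict(state.query_graph),
            "knowledge_graph": {
                "nodes": {
                    nid: {
                        "name": n.name,
                        "categories": sorted(n.categories),
                        "attributes": [
                            {"name": a.name, "value": a.value, "source": a.source}
                            for a in n.attributes
                        ],
                    }
                    for nid, n in sorted(kg.nodes.items())
                },
                "edges": {eid: _edge_to_dict(e) for eid, e in sorted(kg.edges.items())},
            },
            "results": [
                {
                    "node_bindings": dict(sorted(r.node_bindings.items())),
                    "edge_bindings": {
                        k: sorted(v) for k, v in sorted(r.edge_bindings.items())
                    },
                    "score": (
                        None
                        if r.score is None or (isinstance(r.score, float) and math.isnan(r.score))
                        else r.score
                    ),
                }
                for r in state.results
            ],
        },
        "logs": [entry.as_dict() for entry in state.log],
    }


def write_response(state: ReasoningState, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(response_to_dict(state), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_response(path: PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
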