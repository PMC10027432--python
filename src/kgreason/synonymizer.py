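"""Identifier synonym clustering and graph canonicalization.

Overlapping controlled vocabularies mean one concept often has several valid
CURIEs (MONDO:0019391, DOID:13636 and ORPHANET:84 all name Fanconi anemia).
The synonymizer partitions identifiers into equivalence clusters using
pairwise assertions (same-as edges, externally supplied cluster files,
identical node names), guarded by semantic-type compatibility, and assigns
each cluster a canonical representative so graphs from different providers
can be merged without redundant nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set

from .graph import ConceptNode, KnowledgeGraph, merge_graphs
from .hierarchy import CATEGORY, OntologyHierarchy

logger = logging.getLogger(__name__)

EVIDENCE_KINDS = ("same_as_edge", "external_cluster", "identical_name")

# Canonical-representative preference: clusters pick the member whose CURIE
# prefix appears earliest here; unlisted prefixes rank after listed ones,
# final tie-break is lexicographic.
DEFAULT_PREFIX_PRIORITY = (
    "MONDO",
    "DOID",
    "ORPHANET",
    "CHEMBL.COMPOUND",
    "DRUGBANK",
    "UNIPROTKB",
    "NCBIGENE",
    "HP",
    "GO",
)


@dataclass(frozen=True)
class EquivalenceAssertion:
    id_a: str
    id_b: str
    evidence: str = "external_cluster"

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError(f"self-assertion for {self.id_a}")
        if self.evidence not in EVIDENCE_KINDS:
            raise ValueError(f"unknown evidence kind {self.evidence!r}")


@dataclass
class SynonymCluster:
    members: FrozenSet[str]
    canonical_id: str
    category_profile: FrozenSet[str]


class _DisjointSet:
    def __init__(self):
        self.parent: Dict[str, str] = {}

    def add(self, x: str) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _curie_prefix(curie: str) -> str:
    return curie.split(":", 1)[0] if ":" in curie else curie


class Synonymizer:
    """A partition of identifiers into synonym clusters with canonical ids."""

    def __init__(self, clusters: Sequence[SynonymCluster]):
        self.clusters = list(clusters)
        self._by_member: Dict[str, SynonymCluster] = {}
        for c in self.clusters:
            for m in c.members:
                if m in self._by_member:
                    raise ValueError(f"identifier {m} appears in two clusters")
                self._by_member[m] = c

    def get_canonical(self, identifier: str) -> str:
        """Canonical id of the cluster containing ``identifier``.

        Unknown identifiers are their own degenerate singleton and map to
        themselves.
        """
        cluster = self._by_member.get(identifier)
        return cluster.canonical_id if cluster is not None else identifier

    def cluster_of(self, identifier: str) -> Optional[SynonymCluster]:
        return self._by_member.get(identifier)

    def all_ids(self) -> Set[str]:
        return set(self._by_member)


def _pick_canonical(members: Iterable[str], prefix_priority: Sequence[str]) -> str:
    rank = {p: i for i, p in enumerate(prefix_priority)}
    return min(
        members,
        key=lambda m: (rank.get(_curie_prefix(m), len(prefix_priority)), m),
    )


def _ancestor_closure(
    categories: Set[str], hierarchy: OntologyHierarchy
) -> Set[str]:
    closure: Set[str] = set()
    for c in categories:
        if hierarchy.has_term(CATEGORY, c):
            closure |= hierarchy.ancestors(CATEGORY, c)
        else:
            closure.add(c)
    closure.discard(hierarchy.roots.get(CATEGORY))
    return closure


def build_synonymizer(
    nodes: Sequence[ConceptNode],
    assertions: Sequence[EquivalenceAssertion],
    hierarchy: OntologyHierarchy,
    prefix_priority: Sequence[str] = DEFAULT_PREFIX_PRIORITY,
) -> Synonymizer:
    """Cluster identifiers by disjoint-set merge over equivalence assertions.

    A merge is applied only when the two sides' category profiles are
    compatible: their ancestor closures (excluding the namespace root, so
    that a universal top category cannot justify any merge) must intersect.
    Identifiers that appear only in assertions (external vocabulary entries
    with no category information) are always compatible. Assertions of kind
    ``identical_name`` are additionally generated internally for nodes whose
    names are byte-identical.
    """
    node_by_id = {n.id: n for n in nodes}

    all_assertions: List[EquivalenceAssertion] = list(assertions)
    by_name: Dict[str, List[str]] = {}
    for n in nodes:
        by_name.setdefault(n.name, []).append(n.id)
    for name, ids in sorted(by_name.items()):
        if len(ids) > 1:
            ids = sorted(ids)
            anchor = ids[0]
            for other in ids[1:]:
                all_assertions.append(
                    EquivalenceAssertion(anchor, other, "identical_name")
                )

    dsu = _DisjointSet()
    for n in nodes:
        dsu.add(n.id)
    for a in all_assertions:
        dsu.add(a.id_a)
        dsu.add(a.id_b)

    # category profile per current cluster root, updated as merges happen
    def profile_closure(identifier: str) -> Set[str]:
        node = node_by_id.get(identifier)
        if node is None:
            return set()
        return _ancestor_closure(node.categories, hierarchy)

    closures: Dict[str, Set[str]] = {i: profile_closure(i) for i in dsu.parent}
    root_closure: Dict[str, Set[str]] = {i: set(closures[i]) for i in dsu.parent}

    # process deterministically: sorted assertion list
    for a in sorted(all_assertions, key=lambda x: (x.id_a, x.id_b, x.evidence)):
        ra, rb = dsu.find(a.id_a), dsu.find(a.id_b)
        if ra == rb:
            continue
        ca, cb = root_closure[ra], root_closure[rb]
        if ca and cb and not (ca & cb):
            logger.info(
                "skipping incompatible merge %s ~ %s (%s): disjoint category profiles",
                a.id_a,
                a.id_b,
                a.evidence,
            )
            continue
        dsu.union(ra, rb)
        r = dsu.find(ra)
        root_closure[r] = ca | cb

    groups: Dict[str, Set[str]] = {}
    for identifier in dsu.parent:
        groups.setdefault(dsu.find(identifier), set()).add(identifier)

    clusters = []
    for members in groups.values():
        profile: Set[str] = set()
        for m in members:
            node = node_by_id.get(m)
            if node is not None:
                profile |= node.categories
        clusters.append(
            SynonymCluster(
                members=frozenset(members),
                canonical_id=_pick_canonical(members, prefix_priority),
                category_profile=frozenset(profile),
            )
        )
    clusters.sort(key=lambda c: c.canonical_id)
    return Synonymizer(clusters)


def get_canonical(syn: Synonymizer, identifier: str) -> str:
    return syn.get_canonical(identifier)


def canonicalize_graph(kg: KnowledgeGraph, syn: Synonymizer) -> KnowledgeGraph:
    """Rewrite every node id to its canonical id and merge synonym clusters.

    Merged nodes keep the canonical member's name when available, pool their
    categories and attributes, and have their incident edges re-pointed;
    re-pointed edges are then deduplicated by triple+source identity.
    Self-loops created by merging two synonymous endpoints are retained.
    """
    from dataclasses import replace

    out = KnowledgeGraph()
    for node in kg.nodes.values():
        cid = syn.get_canonical(node.id)
        name = node.name
        if cid != node.id and cid in kg.nodes:
            name = kg.nodes[cid].name
        existing = out.nodes.get(cid)
        if existing is None:
            out.add_node(
                ConceptNode(cid, name, set(node.categories), list(node.attributes))
            )
        else:
            if cid == node.id:
                existing.name = node.name
            existing.categories |= node.categories
            existing.attributes = existing.attributes + [
                a for a in node.attributes if a not in existing.attributes
            ]
    repointed = KnowledgeGraph()
    for n in out.nodes.values():
        repointed.add_node(n)
    for edge in kg.edges.values():
        repointed.add_edge(
            replace(
                edge,
                subject=syn.get_canonical(edge.subject),
                object=syn.get_canonical(edge.object),
                attributes=list(edge.attributes),
            )
        )
    return merge_graphs([repointed])
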