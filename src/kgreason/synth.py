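"""Deterministic synthetic fixture generator.

Emits everything the engine consumes — a category/predicate hierarchy, a
provider bundle (node/edge/meta-triple tables), synonym-equivalence
assertions, a literature co-occurrence index, a reference query message and
a ground-truth manifest — from a single seed.  The generated world models a
small drug-repurposing corpus: a pinned drug interacts with a designated set
of subject proteins; a planted *hub* disease is associated with m of those s
subject proteins (an enrichment motif that Fisher-exact overlay should
recover), while distractor diseases attach to one protein each; some
diseases carry duplicate identifiers from alternative vocabularies, joined
by same-as assertions, exercising the synonymizer; edges carry publication
lists drawn from a zero-inflated geometric distribution; and name pairs on
the planted path receive elevated co-occurrence counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import Attribute, ConceptNode, KnowledgeEdge, KnowledgeGraph, MetaTriple
from .hierarchy import CATEGORY, PREDICATE, OntologyHierarchy
from .io import (
    write_assertions,
    write_cooccurrence_index,
    write_hierarchy,
    write_kg_tables,
    write_meta_triples,
)
from .overlay import CooccurrenceIndex
from .providers import GraphProvider
from .synonymizer import EquivalenceAssertion

DRUG_CAT = "Drug"
PROTEIN_CAT = "Protein"
DISEASE_CAT = "Disease"


@dataclass
class SynthConfig:
    seed: int = 0
    n_drugs: int = 4
    n_proteins: int = 20
    n_diseases: int = 12
    motif_subjects: int = 6  # s: proteins designated as the subject set
    motif_connections: int = 5  # m: subjects the hub disease attaches to
    synonym_cluster_count: int = 3
    synonym_cluster_size: int = 3
    # zero-inflated geometric publication counts
    publication_zero_inflation: float = 0.5
    publication_geometric_mean: float = 3.0
    # co-occurrence index shape
    cooccurrence_total: int = 10000
    cooccurrence_association: float = 0.8  # planted pair count / min(term counts)

    def __post_init__(self):
        for name in ("n_drugs", "n_proteins", "n_diseases", "motif_subjects",
                     "motif_connections", "synonym_cluster_count",
                     "synonym_cluster_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.motif_connections > self.motif_subjects:
            raise ValueError(
                "motif_connections (m) cannot exceed motif_subjects (s)"
            )
        if self.motif_subjects > self.n_proteins:
            raise ValueError("motif_subjects cannot exceed n_proteins")
        if self.synonym_cluster_count > self.n_diseases - 1:
            raise ValueError("too many synonym clusters for the disease count")


@dataclass
class GroundTruthManifest:
    hub_id: str
    motif_subject_ids: List[str]
    motif_connection_ids: List[str]
    distractor_object_ids: List[str]
    pinned_drug_id: str
    expected_result_count: int
    synonym_clusters: List[List[str]]

    def as_dict(self) -> dict:
        return {
            "hub_id": self.hub_id,
            "motif_subject_ids": self.motif_subject_ids,
            "motif_connection_ids": self.motif_connection_ids,
            "distractor_object_ids": self.distractor_object_ids,
            "pinned_drug_id": self.pinned_drug_id,
            "expected_result_count": self.expected_result_count,
            "synonym_clusters": self.synonym_clusters,
        }


@dataclass
class SyntheticBundle:
    config: SynthConfig
    hierarchy: OntologyHierarchy
    graph: KnowledgeGraph
    meta_triples: List[MetaTriple]
    assertions: List[EquivalenceAssertion]
    cooccurrence: CooccurrenceIndex
    manifest: GroundTruthManifest
    query_message: dict

    def provider(self, name: str = "synthkp") -> GraphProvider:
        return GraphProvider(name, self.graph, self.hierarchy, self.meta_triples)


def default_hierarchy() -> OntologyHierarchy:
    """The small category/predicate world used by the generator."""
    h = OntologyHierarchy()
    h.add_term(CATEGORY, "NamedThing")
    for depth1 in ("ChemicalEntity", "BiologicalEntity", "DiseaseOrPhenotypicFeature"):
        h.add_term(CATEGORY, depth1, ["NamedThing"])
    h.add_term(CATEGORY, DRUG_CAT, ["ChemicalEntity"])
    h.add_term(CATEGORY, PROTEIN_CAT, ["BiologicalEntity"])
    h.add_term(CATEGORY, DISEASE_CAT, ["DiseaseOrPhenotypicFeature"])
    h.add_term(PREDICATE, "related_to")
    for p in ("interacts_with", "associated_with", "treats"):
        h.add_term(PREDICATE, p, ["related_to"])
    h.add_term(PREDICATE, "physically_interacts_with", ["interacts_with"])
    h.validate()
    return h


def _publication_count(rng: np.random.Generator, config: SynthConfig) -> int:
    if rng.random() < config.publication_zero_inflation:
        return 0
    p = 1.0 / config.publication_geometric_mean
    return int(rng.geometric(p))


def generate_synthetic_kg(config: SynthConfig) -> SyntheticBundle:
    """Build the synthetic world in memory (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    hierarchy = default_hierarchy()
    kg = KnowledgeGraph()

    drugs = [f"CHEMBL.COMPOUND:D{i:04d}" for i in range(config.n_drugs)]
    proteins = [f"UNIPROTKB:P{i:04d}" for i in range(config.n_proteins)]
    diseases = [f"MONDO:{7000000 + i:07d}" for i in range(config.n_diseases)]

    for i, d in enumerate(drugs):
        kg.add_node(ConceptNode(d, f"drug {i}", {DRUG_CAT}))
    for i, p in enumerate(proteins):
        kg.add_node(ConceptNode(p, f"protein {i}", {PROTEIN_CAT}))
    for i, z in enumerate(diseases):
        kg.add_node(ConceptNode(z, f"disease {i}", {DISEASE_CAT}))

    hub = diseases[0]
    subjects = proteins[: config.motif_subjects]
    connected = subjects[: config.motif_connections]
    pinned_drug = drugs[0]

    pub_counter = 0
    edge_counter = 0

    def add_edge(subject: str, obj: str, predicate: str, source: str) -> None:
        nonlocal pub_counter, edge_counter
        attrs: List[Attribute] = []
        n_pubs = _publication_count(rng, config)
        if n_pubs:
            pubs = [f"PMID:{pub_counter + j}" for j in range(n_pubs)]
            pub_counter += n_pubs
            attrs.append(Attribute("publications", pubs, source="synth"))
        kg.add_edge(
            KnowledgeEdge(
                id=f"e{edge_counter:05d}",
                subject=subject,
                object=obj,
                predicate=predicate,
                primary_source=source,
                attributes=attrs,
            )
        )
        edge_counter += 1

    # pinned drug interacts with every motif subject protein
    interact_preds = ["interacts_with", "physically_interacts_with"]
    for prot in subjects:
        add_edge(pinned_drug, prot, interact_preds[int(rng.integers(2))], "synth_kp")
    # other drugs pick up two random proteins each
    for d in drugs[1:]:
        picks = rng.choice(config.n_proteins, size=2, replace=False)
        for idx in sorted(int(x) for x in picks):
            add_edge(d, proteins[idx], interact_preds[int(rng.integers(2))], "synth_kp")

    # planted enrichment motif: hub disease attaches to m of the s subjects
    for prot in connected:
        add_edge(prot, hub, "associated_with", "synth_kp")
    # distractor diseases: half attach to one subject protein, half to one
    # non-subject protein (so both kinds of candidates exist at prune time)
    distractors = diseases[1:]
    non_subject = proteins[config.motif_subjects:]
    for j, dis in enumerate(distractors):
        if j % 2 == 0 and non_subject:
            prot = non_subject[int(rng.integers(len(non_subject)))]
        else:
            prot = subjects[int(rng.integers(len(subjects)))]
        add_edge(prot, dis, "associated_with", "synth_kp")

    # synonym clusters: duplicate identifiers for the first few distractor
    # diseases, chained by same-as assertions, each duplicate re-asserting
    # one of the original's edges from a second vocabulary
    assertions: List[EquivalenceAssertion] = []
    clusters: List[List[str]] = []
    alt_prefixes = ["DOID", "ORPHANET", "UMLS", "MESH"]
    for c in range(config.synonym_cluster_count):
        original = distractors[c]
        original_idx = diseases.index(original)
        members = [original]
        for k in range(config.synonym_cluster_size - 1):
            dup = f"{alt_prefixes[k % len(alt_prefixes)]}:{80000 + 10 * c + k}"
            kg.add_node(
                ConceptNode(dup, kg.nodes[original].name, {DISEASE_CAT})
            )
            # duplicate carries the same association, asserted by another source
            orig_edges = [
                e for e in kg.edges.values()
                if e.object == original and not e.is_virtual
            ]
            if orig_edges:
                src_edge = sorted(orig_edges, key=lambda e: e.id)[0]
                add_edge(src_edge.subject, dup, src_edge.predicate, "dup_kp")
            # chain: previous member <-> new member (tests transitivity)
            assertions.append(
                EquivalenceAssertion(members[-1], dup, "same_as_edge")
            )
            members.append(dup)
        clusters.append(members)

    meta = sorted(
        {
            MetaTriple(
                sc, e.predicate, oc
            )
            for e in kg.edges.values()
            for sc in kg.nodes[e.subject].categories
            for oc in kg.nodes[e.object].categories
        },
        key=lambda m: (m.subject_category, m.predicate, m.object_category),
    )

    # co-occurrence index over node names
    index = CooccurrenceIndex(total=config.cooccurrence_total)
    names = sorted({n.name for n in kg.nodes.values()})
    for name in names:
        index.add_term(name, int(rng.integers(20, 200)))
    drug_name = kg.nodes[pinned_drug].name
    for prot in subjects:
        pn = kg.nodes[prot].name
        lo = min(index.occurrence[drug_name], index.occurrence[pn])
        index.add_pair(drug_name, pn, max(1, int(config.cooccurrence_association * lo)))
    # sparse background pairs
    for _ in range(len(names)):
        i, j = rng.integers(len(names)), rng.integers(len(names))
        if i == j:
            continue
        t1, t2 = names[int(i)], names[int(j)]
        if index.pair_count(t1, t2) == 0:
            index.add_pair(t1, t2, int(rng.integers(1, 4)))
    index.validate()

    # reference 1-hop query: proteins interacting with the pinned drug
    query_message = {
        "message": {
            "query_graph": {
                "nodes": {
                    "n0": {"ids": [pinned_drug]},
                    "n1": {"categories": [PROTEIN_CAT]},
                },
                "edges": {
                    "e0": {
                        "subject": "n0",
                        "object": "n1",
                        "predicates": ["interacts_with"],
                    }
                },
            }
        }
    }
    interact_ok = hierarchy.descendants(PREDICATE, "interacts_with")
    expected = {
        e.object
        for e in kg.edges.values()
        if e.subject == pinned_drug and e.predicate in interact_ok
    } | {
        e.subject
        for e in kg.edges.values()
        if e.object == pinned_drug and e.predicate in interact_ok
    }

    manifest = GroundTruthManifest(
        hub_id=hub,
        motif_subject_ids=list(subjects),
        motif_connection_ids=list(connected),
        distractor_object_ids=list(distractors),
        pinned_drug_id=pinned_drug,
        expected_result_count=len(expected),
        synonym_clusters=clusters,
    )
    return SyntheticBundle(
        config=config,
        hierarchy=hierarchy,
        graph=kg,
        meta_triples=meta,
        assertions=assertions,
        cooccurrence=index,
        manifest=manifest,
        query_message=query_message,
    )


def write_bundle(bundle: SyntheticBundle, directory) -> Dict[str, Path]:
    """Write the bundle to disk as plain-text tables and JSON files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    kp = d / "kp0"
    kp.mkdir(exist_ok=True)
    paths = {
        "categories": d / "categories.tsv",
        "predicates": d / "predicates.tsv",
        "nodes": kp / "nodes.tsv",
        "edges": kp / "edges.tsv",
        "meta_triples": kp / "meta_triples.tsv",
        "assertions": d / "assertions.tsv",
        "cooccurrence": d / "cooccurrence.tsv",
        "query": d / "query.json",
        "manifest": d / "manifest.json",
        "provider_dir": kp,
    }
    write_hierarchy(bundle.hierarchy, paths["categories"], paths["predicates"])
    write_kg_tables(bundle.graph, paths["nodes"], paths["edges"])
    write_meta_triples(bundle.meta_triples, paths["meta_triples"])
    write_assertions(bundle.assertions, paths["assertions"])
    write_cooccurrence_index(bundle.cooccurrence, paths["cooccurrence"])
    with open(paths["query"], "w", encoding="utf-8") as fh:
        json.dump(bundle.query_message, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest.as_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
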