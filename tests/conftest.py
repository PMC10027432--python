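"""Shared fixtures: a small ontology world, hand-built toy graphs, and the
seeded synthetic bundle."""

from __future__ import annotations

import pytest

from kgreason import (
    ConceptNode,
    KnowledgeEdge,
    KnowledgeGraph,
    SynthConfig,
    generate_synthetic_kg,
)
from kgreason.synth import default_hierarchy


@pytest.fixture(scope="session")
def hierarchy():
    return default_hierarchy()


def build_kg(nodes, edges):
    """nodes: (id, category) or (id, name, category); edges: (id, subj, obj,
    predicate) or (id, subj, obj, predicate, source)."""
    kg = KnowledgeGraph()
    for spec in nodes:
        if len(spec) == 2:
            nid, cat = spec
            name = nid
        else:
            nid, name, cat = spec
        kg.add_node(ConceptNode(nid, name, {cat}))
    for spec in edges:
        eid, s, o, p = spec[:4]
        source = spec[4] if len(spec) > 4 else "test"
        kg.add_edge(KnowledgeEdge(eid, s, o, p, primary_source=source))
    return kg


@pytest.fixture
def kg_factory():
    return build_kg


@pytest.fixture(scope="session")
def bundle():
    """The reference synthetic world (fixed seed, default study conditions)."""
    return generate_synthetic_kg(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def figure_world(hierarchy):
    """A drug with interacts_with-family edges to three proteins, plus
    distractor nodes and edges that must not produce results."""
    kg = build_kg(
        nodes=[
            ("CHEMBL.COMPOUND:CHEMBL112", "acetaminophen", "Drug"),
            ("UNIPROTKB:P23219", "PTGS1", "Protein"),
            ("UNIPROTKB:P35354", "PTGS2", "Protein"),
            ("UNIPROTKB:P08684", "CYP3A4", "Protein"),
            ("MONDO:0005301", "headache", "Disease"),
            ("UNIPROTKB:P99999", "CYCS", "Protein"),
        ],
        edges=[
            ("e1", "CHEMBL.COMPOUND:CHEMBL112", "UNIPROTKB:P23219", "interacts_with"),
            ("e2", "CHEMBL.COMPOUND:CHEMBL112", "UNIPROTKB:P35354",
             "physically_interacts_with"),
            ("e3", "UNIPROTKB:P08684", "CHEMBL.COMPOUND:CHEMBL112",
             "interacts_with"),
            # distractors: wrong predicate, wrong category
            ("e4", "CHEMBL.COMPOUND:CHEMBL112", "MONDO:0005301", "treats"),
            ("e5", "UNIPROTKB:P99999", "MONDO:0005301", "associated_with"),
        ],
    )
    return kg
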