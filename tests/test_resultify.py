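"""Subgraph fulfillment: the worked one-hop example, direction semantics,
parallel-edge grouping, and equivalence with the brute-force oracle on random
worlds."""

import numpy as np
import pytest

from kgreason import (
    ConceptNode,
    KnowledgeEdge,
    KnowledgeGraph,
    QueryEdge,
    QueryGraph,
    QueryNode,
    binding_fulfills,
    enumerate_results,
)

from .oracles import enumerate_bindings_oracle

ACET = "CHEMBL.COMPOUND:CHEMBL112"


def _one_hop_query(ids=(ACET,), predicates=("interacts_with",)):
    qg = QueryGraph()
    qg.add_node(QueryNode("n0", ids=list(ids)))
    qg.add_node(QueryNode("n1", categories=["Protein"]))
    qg.add_edge(QueryEdge("e0", "n0", "n1", predicates=list(predicates)))
    return qg


class TestWorkedExample:
    def test_three_proteins_fulfill_one_hop_query(self, figure_world, hierarchy):
        results = enumerate_results(_one_hop_query(), figure_world, hierarchy)
        assert len(results) == 3
        bound = {r.node_bindings["n1"] for r in results}
        assert bound == {"UNIPROTKB:P23219", "UNIPROTKB:P35354", "UNIPROTKB:P08684"}

    def test_descendant_predicate_fulfills(self, figure_world, hierarchy):
        # P35354 is reached only via physically_interacts_with
        results = enumerate_results(_one_hop_query(), figure_world, hierarchy)
        assert "UNIPROTKB:P35354" in {r.node_bindings["n1"] for r in results}

    def test_direction_mode_controls_reverse_edges(self, figure_world, hierarchy):
        # P08684 -> acetaminophen is stored in reverse orientation
        ignore = enumerate_results(
            _one_hop_query(), figure_world, hierarchy, ignore_edge_direction=True
        )
        enforce = enumerate_results(
            _one_hop_query(), figure_world, hierarchy, ignore_edge_direction=False
        )
        assert {r.node_bindings["n1"] for r in ignore} - {
            r.node_bindings["n1"] for r in enforce
        } == {"UNIPROTKB:P08684"}
        assert len(enforce) == 2

    def test_no_predicate_match_yields_zero_results(self, figure_world, hierarchy):
        results = enumerate_results(
            _one_hop_query(predicates=("treats",)), figure_world, hierarchy
        )
        # the only treats edge points at a Disease, not a Protein
        assert results == []


class TestBindingFulfills:
    def test_emitted_results_are_sound(self, figure_world, hierarchy):
        qg = _one_hop_query()
        for r in enumerate_results(qg, figure_world, hierarchy):
            assert binding_fulfills(qg, figure_world, r.node_bindings, hierarchy)

    def test_pin_violation_rejected(self, figure_world, hierarchy):
        qg = _one_hop_query()
        binding = {"n0": "UNIPROTKB:P23219", "n1": "UNIPROTKB:P35354"}
        assert not binding_fulfills(qg, figure_world, binding, hierarchy)

    def test_ancestor_predicate_rejected_where_descendant_required(
        self, kg_factory, hierarchy
    ):
        kg = kg_factory(
            [("D:1", "Drug"), ("P:1", "Protein")],
            [("e1", "D:1", "P:1", "interacts_with")],
        )
        qg = _one_hop_query(ids=("D:1",), predicates=("physically_interacts_with",))
        assert not binding_fulfills(qg, kg, {"n0": "D:1", "n1": "P:1"}, hierarchy)

    def test_unknown_binding_id_raises(self, figure_world, hierarchy):
        qg = _one_hop_query()
        with pytest.raises(ValueError, match="unknown KG node"):
            binding_fulfills(qg, figure_world, {"n0": ACET, "n1": "GHOST:1"}, hierarchy)


class TestParallelEdges:
    def test_parallel_edges_grouped_into_one_result(self, kg_factory, hierarchy):
        kg = kg_factory(
            [("D:1", "Drug"), ("P:1", "Protein")],
            [
                ("e1", "D:1", "P:1", "interacts_with", "kp1"),
                ("e2", "D:1", "P:1", "physically_interacts_with", "kp2"),
            ],
        )
        results = enumerate_results(_one_hop_query(ids=("D:1",)), kg, hierarchy)
        assert len(results) == 1
        assert results[0].edge_bindings["e0"] == {"e1", "e2"}


class TestVirtualEdgeAttachment:
    def test_virtual_edges_ride_along_under_their_keys(self, kg_factory, hierarchy):
        kg = kg_factory(
            [("D:1", "Drug"), ("P:1", "Protein")],
            [("e1", "D:1", "P:1", "interacts_with")],
        )
        kg.add_edge(KnowledgeEdge("ve", "D:1", "P:1", "related_to",
                                  is_virtual=True, qedge_key="v0"))
        results = enumerate_results(_one_hop_query(ids=("D:1",)), kg, hierarchy)
        assert results[0].edge_bindings["v0"] == {"ve"}
        # the virtual edge never fulfills the real query edge
        assert results[0].edge_bindings["e0"] == {"e1"}


def _random_world(rng, hierarchy):
    cats = ["Drug", "Protein", "Disease"]
    preds = ["interacts_with", "physically_interacts_with", "associated_with",
             "treats", "related_to"]
    n_nodes = int(rng.integers(3, 9))
    kg = KnowledgeGraph()
    for i in range(n_nodes):
        kg.add_node(ConceptNode(f"N:{i}", f"node {i}",
                                {cats[int(rng.integers(3))]}))
    n_edges = int(rng.integers(2, 13))
    for j in range(n_edges):
        s = f"N:{int(rng.integers(n_nodes))}"
        o = f"N:{int(rng.integers(n_nodes))}"
        kg.add_edge(KnowledgeEdge(f"E:{j}", s, o, preds[int(rng.integers(5))],
                                  primary_source=f"kp{int(rng.integers(2))}"))
    return kg


def _random_query(rng, kg, shape):
    cats = [None, ["Drug"], ["Protein"], ["Disease"], ["NamedThing"]]
    preds = [None, ["interacts_with"], ["associated_with"], ["related_to"]]
    node_ids = sorted(kg.nodes)

    def qnode(key, pin_chance=0.4):
        if rng.random() < pin_chance:
            return QueryNode(key, ids=[node_ids[int(rng.integers(len(node_ids)))]])
        return QueryNode(key, categories=cats[int(rng.integers(len(cats)))])

    qg = QueryGraph()
    if shape == "one_hop":
        qg.add_node(qnode("n0", 1.0))
        qg.add_node(qnode("n1", 0.0))
        qg.add_edge(QueryEdge("e0", "n0", "n1", preds[int(rng.integers(4))]))
    elif shape == "path":
        for k in ("n0", "n1", "n2"):
            qg.add_node(qnode(k))
        qg.add_edge(QueryEdge("e0", "n0", "n1", preds[int(rng.integers(4))]))
        qg.add_edge(QueryEdge("e1", "n1", "n2", preds[int(rng.integers(4))]))
    elif shape == "cycle":
        for k in ("n0", "n1", "n2"):
            qg.add_node(qnode(k))
        qg.add_edge(QueryEdge("e0", "n0", "n1", preds[int(rng.integers(4))]))
        qg.add_edge(QueryEdge("e1", "n1", "n2", preds[int(rng.integers(4))]))
        qg.add_edge(QueryEdge("e2", "n2", "n0", preds[int(rng.integers(4))]))
    else:  # parallel
        qg.add_node(qnode("n0"))
        qg.add_node(qnode("n1", 0.0))
        qg.add_edge(QueryEdge("e0", "n0", "n1", preds[int(rng.integers(4))]))
        qg.add_edge(QueryEdge("e1", "n0", "n1", preds[int(rng.integers(4))]))
    return qg


class TestOracleEquivalence:
    @pytest.mark.parametrize("shape", ["one_hop", "path", "cycle", "parallel"])
    @pytest.mark.parametrize("ignore_direction", [True, False])
    def test_matches_brute_force_on_random_worlds(
        self, hierarchy, shape, ignore_direction
    ):
        """On >=100 random (KG, query) pairs per configuration, the
        backtracking enumerator and the exhaustive oracle agree exactly."""
        n_nonempty = 0
        for seed in range(30):
            rng = np.random.default_rng(10_000 + seed)
            kg = _random_world(rng, hierarchy)
            qg = _random_query(rng, kg, shape)
            got = enumerate_results(
                qg, kg, hierarchy, ignore_edge_direction=ignore_direction
            )
            expected = enumerate_bindings_oracle(qg, kg, hierarchy, ignore_direction)
            got_maps = sorted(tuple(sorted(r.node_bindings.items())) for r in got)
            exp_maps = sorted(tuple(sorted(b.items())) for b in expected)
            assert got_maps == exp_maps, f"seed {seed} shape {shape}"
            # no duplicate binding maps
            assert len(got_maps) == len(set(got_maps))
            n_nonempty += bool(got)
        assert n_nonempty > 0  # the suite exercises non-vacuous cases
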