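"""Overlay statistics: Fisher exact test, Jaccard neighbor sharing,
normalized co-occurrence distance, and virtual-edge mechanics."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from kgreason import (
    ContingencyTable,
    CooccurrenceIndex,
    QueryEdge,
    QueryGraph,
    QueryNode,
    fisher_exact_two_sided,
    jaccard_similarity,
    normalized_cooccurrence_distance,
    overlay_fisher,
    overlay_virtual_edges,
)
from kgreason.overlay import constant_predictor, fisher_enrichment_pvalues
from kgreason.state import ReasoningState

from .oracles import fisher_two_sided_oracle


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_diagonal_two_table(self):
        # enumeration over a in {0,1,2}: 1/6 + 1/6 = 1/3
        assert fisher_exact_two_sided(ContingencyTable(2, 0, 0, 2)) == pytest.approx(
            1 / 3
        )

    def test_diagonal_five_table_matches_enumeration(self):
        expected = fisher_two_sided_oracle(5, 0, 0, 5)
        assert fisher_exact_two_sided(ContingencyTable(5, 0, 0, 5)) == pytest.approx(
            expected, rel=1e-7
        )

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.integers(0, 8), b=st.integers(0, 8),
        c=st.integers(0, 8), d=st.integers(0, 8),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-7)


def _enrichment_world(kg_factory):
    """10-node background: subjects S1..S4 (Protein), objects O1..O3
    (Disease), fillers F1..F3 (Protein). O1 connects to all subjects and
    nothing else; O2 to one subject; O3 to a filler only."""
    nodes = [(f"S:{i}", "Protein") for i in range(1, 5)]
    nodes += [(f"O:{i}", "Disease") for i in range(1, 4)]
    nodes += [(f"F:{i}", "Protein") for i in range(1, 4)]
    edges = [(f"eS{i}", f"S:{i}", "O:1", "associated_with") for i in range(1, 5)]
    edges += [("eO2", "S:1", "O:2", "associated_with")]
    edges += [("eO3", "F:1", "O:3", "associated_with")]
    return kg_factory(nodes, edges)


class TestFisherEnrichment:
    def test_fully_connected_object_attains_smallest_p(self, kg_factory):
        kg = _enrichment_world(kg_factory)
        subjects = {f"S:{i}" for i in range(1, 5)}
        pv = fisher_enrichment_pvalues(kg, subjects, {"O:1", "O:2", "O:3"})
        assert min(pv, key=lambda k: pv[k][0]) == "O:1"
        # O:1's table in the 7-protein population: a=4,b=0,c=0,d=3
        assert pv["O:1"][0] == pytest.approx(fisher_two_sided_oracle(4, 0, 0, 3), rel=1e-7)

    def test_object_without_subject_connection_gets_no_virtual_edge(self, kg_factory):
        kg = _enrichment_world(kg_factory)
        state = _state_with_bindings(kg, subjects={"S:1", "S:2"}, objects={"O:3"})
        overlay_fisher(state, "n0", "n1", kg)
        assert not [e for e in state.answer_kg.edges.values() if e.is_virtual]

    def test_identical_connection_patterns_give_identical_p(self, kg_factory):
        nodes = [("S:1", "Protein"), ("S:2", "Protein"),
                 ("O:1", "Disease"), ("O:2", "Disease")]
        edges = [("e1", "S:1", "O:1", "associated_with"),
                 ("e2", "S:1", "O:2", "associated_with")]
        kg = kg_factory(nodes, edges)
        pv = fisher_enrichment_pvalues(kg, {"S:1", "S:2"}, {"O:1", "O:2"})
        assert pv["O:1"][0] == pytest.approx(pv["O:2"][0])

    def test_empty_binding_is_warned_noop(self, kg_factory):
        kg = _enrichment_world(kg_factory)
        state = _state_with_bindings(kg, subjects=set(), objects={"O:1"})
        overlay_fisher(state, "n0", "n1", kg)
        assert any(e.level == "WARNING" for e in state.log)
        assert not [e for e in state.answer_kg.edges.values() if e.is_virtual]


def _state_with_bindings(kg, subjects, objects):
    qg = QueryGraph()
    qg.add_node(QueryNode("n0", categories=["Protein"]))
    qg.add_node(QueryNode("n1", categories=["Disease"]))
    qg.add_edge(QueryEdge("e0", "n0", "n1"))
    state = ReasoningState(query_graph=qg, answer_kg=kg.copy())
    state.qnode_bindings["n0"] = set(subjects)
    state.qnode_bindings["n1"] = set(objects)
    return state


class TestJaccard:
    def _kg(self, kg_factory):
        nodes = [("VS", "Drug"), ("VE", "Disease"), ("X", "Drug")]
        nodes += [(f"P:{i}", "Protein") for i in range(1, 5)]
        edges = [(f"s{i}", "VS", f"P:{i}", "interacts_with") for i in range(1, 5)]
        # VE adjacent to P:1, P:2 only; a parallel edge must not double-count
        edges += [("t1", "VE", "P:1", "associated_with"),
                  ("t2", "P:2", "VE", "associated_with"),
                  ("t3", "VE", "P:1", "related_to")]
        edges += [("x1", "VS", "X", "related_to")]  # non-protein neighbor ignored
        return kg_factory(nodes, edges)

    def test_half_shared_intermediates(self, kg_factory, hierarchy):
        kg = self._kg(kg_factory)
        assert jaccard_similarity(kg, "VS", "VE", "Protein", hierarchy) == pytest.approx(0.5)

    def test_no_shared_intermediates_is_zero(self, kg_factory, hierarchy):
        kg = self._kg(kg_factory)
        kg.remove_edge("t1"); kg.remove_edge("t2"); kg.remove_edge("t3")
        assert jaccard_similarity(kg, "VS", "VE", "Protein", hierarchy) == 0.0

    def test_all_shared_is_one(self, kg_factory, hierarchy):
        from kgreason import KnowledgeEdge
        kg = self._kg(kg_factory)
        for i in (3, 4):
            kg.add_edge(KnowledgeEdge(f"t{i+2}", "VE", f"P:{i}", "associated_with"))
        assert jaccard_similarity(kg, "VS", "VE", "Protein", hierarchy) == pytest.approx(1.0)

    def test_no_intermediate_neighbors_is_missing(self, kg_factory, hierarchy):
        kg = self._kg(kg_factory)
        assert math.isnan(jaccard_similarity(kg, "X", "VE", "Protein", hierarchy))

    def test_unknown_node_raises(self, kg_factory, hierarchy):
        with pytest.raises(KeyError):
            jaccard_similarity(self._kg(kg_factory), "NOPE", "VE", "Protein", hierarchy)


class TestNGD:
    def _index(self, f1, f2, f12, total):
        idx = CooccurrenceIndex(total=total)
        idx.add_term("t1", f1)
        idx.add_term("t2", f2)
        if f12:
            idx.add_pair("t1", "t2", f12)
        return idx

    def test_identical_support_is_zero(self):
        idx = self._index(7, 7, 7, 1000)
        assert normalized_cooccurrence_distance("t1", "t2", idx) == pytest.approx(0.0)

    def test_closed_form_half(self):
        # max(log 10, log 100) - log 10 = 1 decade; log 1000 - log 10 = 2
        idx = self._index(10, 100, 10, 1000)
        assert normalized_cooccurrence_distance("t1", "t2", idx) == pytest.approx(0.5)

    def test_no_cooccurrence_is_missing(self):
        idx = self._index(10, 100, 0, 1000)
        assert math.isnan(normalized_cooccurrence_distance("t1", "t2", idx))

    def test_absent_term_is_missing(self):
        idx = self._index(10, 100, 10, 1000)
        assert math.isnan(normalized_cooccurrence_distance("t1", "zzz", idx))

    @settings(max_examples=50, derandomize=True)
    @given(f1=st.integers(2, 500), f2=st.integers(2, 500), k=st.integers(1, 100))
    def test_symmetry(self, f1, f2, k):
        f12 = min(f1, f2, k)
        idx = self._index(f1, f2, f12, 10_000)
        d12 = normalized_cooccurrence_distance("t1", "t2", idx)
        d21 = normalized_cooccurrence_distance("t2", "t1", idx)
        assert d12 == pytest.approx(d21)


class TestOverlayVirtualEdges:
    def test_predictor_stub_annotates_every_pair(self, kg_factory):
        kg = _enrichment_world(kg_factory)
        state = _state_with_bindings(kg, subjects={"S:1", "S:2"}, objects={"O:1"})
        overlay_virtual_edges(
            state, "predictor",
            subject_qnode_key="n0", object_qnode_key="n1",
            predictor=constant_predictor(0.7),
        )
        virtuals = [e for e in state.answer_kg.edges.values() if e.is_virtual]
        assert len(virtuals) == 2
        assert all(e.get_attribute("probability_treats").value == 0.7 for e in virtuals)
        assert all(e.qedge_key == "v0" for e in virtuals)

    def test_repeated_overlay_gets_fresh_key_and_keeps_prior(self, kg_factory):
        kg = _enrichment_world(kg_factory)
        state = _state_with_bindings(kg, subjects={"S:1"}, objects={"O:1"})
        overlay_virtual_edges(state, "predictor", subject_qnode_key="n0",
                              object_qnode_key="n1", predictor=constant_predictor(0.7))
        overlay_virtual_edges(state, "predictor", subject_qnode_key="n0",
                              object_qnode_key="n1", predictor=constant_predictor(0.2))
        keys = {e.qedge_key for e in state.answer_kg.edges.values() if e.is_virtual}
        assert keys == {"v0", "v1"}

    def test_overlay_never_mutates_existing_edges(self, kg_factory):
        kg = _enrichment_world(kg_factory)
        state = _state_with_bindings(kg, subjects={"S:1", "S:2"}, objects={"O:1"})
        before = {eid: (e.subject, e.object, e.predicate)
                  for eid, e in state.answer_kg.edges.items()}
        overlay_fisher(state, "n0", "n1", kg)
        for eid, frozen in before.items():
            e = state.answer_kg.edges[eid]
            assert (e.subject, e.object, e.predicate) == frozen

    def test_unknown_kind_rejected(self, kg_factory):
        kg = _enrichment_world(kg_factory)
        state = _state_with_bindings(kg, subjects={"S:1"}, objects={"O:1"})
        with pytest.raises(ValueError, match="unknown overlay kind"):
            overlay_virtual_edges(state, "astrology",
                                  subject_qnode_key="n0", object_qnode_key="n1")

    def test_ngd_overlay_uses_node_names(self, kg_factory, bundle):
        from kgreason.querygraph import query_graph_from_dict
        kg = bundle.graph
        drug = bundle.manifest.pinned_drug_id
        prot = bundle.manifest.motif_subject_ids[0]
        state = _state_with_bindings(kg, subjects={drug}, objects={prot})
        overlay_virtual_edges(
            state, "ngd", subject_qnode_key="n0", object_qnode_key="n1",
            cooccurrence_index=bundle.cooccurrence,
        )
        virtuals = [e for e in state.answer_kg.edges.values() if e.is_virtual]
        assert len(virtuals) == 1
        assert virtuals[0].get_attribute("ngd").value >= 0.0
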