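"""Expansion: provider routing, adaptive prune thresholds, breadth-first
fulfillment, Fisher-guided pruning and the provider timeout contract."""

import time

import pytest

from kgreason import (
    EngineConfig,
    GraphProvider,
    KnowledgeGraph,
    QueryEdge,
    QueryGraph,
    QueryNode,
    default_prune_threshold,
    expand,
    prune_qedge_answers,
    select_providers,
)
from kgreason.providers import LookupRequest
from kgreason.state import ReasoningState


def _qg(subject_pin=None, object_pin=None, subject_cats=None, object_cats=None,
        predicates=None):
    qg = QueryGraph()
    qg.add_node(QueryNode("n0", ids=subject_pin, categories=subject_cats))
    qg.add_node(QueryNode("n1", ids=object_pin, categories=object_cats))
    qg.add_edge(QueryEdge("e0", "n0", "n1", predicates=predicates))
    return qg


@pytest.fixture
def drug_protein_provider(kg_factory, hierarchy):
    kg = kg_factory(
        [("D:1", "Drug"), ("P:1", "Protein"), ("P:2", "Protein"), ("P:3", "Protein")],
        [
            ("e1", "D:1", "P:1", "interacts_with"),
            ("e2", "D:1", "P:2", "physically_interacts_with"),
            ("e3", "P:3", "D:1", "interacts_with"),
        ],
    )
    return GraphProvider("kp_dp", kg, hierarchy)


class TestSelectProviders:
    def test_matching_meta_triple_selects(self, drug_protein_provider, hierarchy):
        qg = _qg(subject_pin=["D:1"], object_cats=["Protein"])
        sel = select_providers(qg.edges["e0"], qg, [drug_protein_provider], hierarchy)
        assert sel == [drug_protein_provider]

    def test_unsatisfiable_predicate_deselects(self, drug_protein_provider, hierarchy):
        qg = _qg(subject_pin=["D:1"], object_cats=["Protein"], predicates=["treats"])
        assert not select_providers(
            qg.edges["e0"], qg, [drug_protein_provider], hierarchy
        )

    def test_root_categories_select_everything(self, drug_protein_provider, hierarchy):
        qg = _qg(subject_cats=["NamedThing"], object_cats=["NamedThing"],
                 subject_pin=None)
        qg.nodes["n0"].ids = ["D:1"]
        sel = select_providers(qg.edges["e0"], qg, [drug_protein_provider], hierarchy)
        assert sel == [drug_protein_provider]

    def test_orientation_agnostic(self, drug_protein_provider, hierarchy):
        # provider meta-triples are Drug->Protein; a Protein->Drug qedge matches
        qg = _qg(subject_cats=["Protein"], object_pin=["D:1"])
        sel = select_providers(qg.edges["e0"], qg, [drug_protein_provider], hierarchy)
        assert sel == [drug_protein_provider]


class TestDefaultPruneThreshold:
    def test_doubly_pinned_is_5000(self, hierarchy):
        qg = _qg(subject_pin=["D:1"], object_pin=["P:1"])
        assert default_prune_threshold(
            qg.edges["e0"], qg, hierarchy, EngineConfig()
        ) == 5000

    def test_unconstrained_is_100(self, hierarchy):
        qg = _qg(subject_pin=["D:1"])
        assert default_prune_threshold(
            qg.edges["e0"], qg, hierarchy, EngineConfig()
        ) == 100

    def test_root_terms_count_as_unconstrained(self, hierarchy):
        qg = _qg(subject_pin=["D:1"], object_cats=["NamedThing"],
                 predicates=["related_to"])
        assert default_prune_threshold(
            qg.edges["e0"], qg, hierarchy, EngineConfig()
        ) == 100

    def test_prevalent_category_is_200(self, hierarchy):
        # ChemicalEntity is one generation below the category root
        qg = _qg(subject_pin=["P:1"], object_cats=["ChemicalEntity"])
        assert default_prune_threshold(
            qg.edges["e0"], qg, hierarchy, EngineConfig()
        ) == 200

    def test_specific_category_is_500(self, hierarchy):
        qg = _qg(subject_pin=["D:1"], object_cats=["Protein"],
                 predicates=["interacts_with"])
        assert default_prune_threshold(
            qg.edges["e0"], qg, hierarchy, EngineConfig()
        ) == 500

    def test_config_override_wins(self, hierarchy):
        qg = _qg(subject_pin=["D:1"], object_pin=["P:1"])
        assert default_prune_threshold(
            qg.edges["e0"], qg, hierarchy, EngineConfig(prune_threshold=42)
        ) == 42


class TestExpand:
    def test_one_hop_pinned_retrieves_all_matching_triples(
        self, drug_protein_provider, hierarchy
    ):
        qg = _qg(subject_pin=["D:1"], object_cats=["Protein"],
                 predicates=["interacts_with"])
        state = ReasoningState(query_graph=qg)
        expand(state, [drug_protein_provider], hierarchy, None, EngineConfig())
        assert len(state.answer_kg.nodes) == 4
        assert len(state.answer_kg.edges) == 3
        assert state.qedge_bindings["e0"] == {"e1", "e2", "e3"}

    def test_threshold_two_retains_two_triples(self, drug_protein_provider, hierarchy):
        qg = _qg(subject_pin=["D:1"], object_cats=["Protein"])
        state = ReasoningState(query_graph=qg)
        expand(state, [drug_protein_provider], hierarchy, None,
               EngineConfig(prune_threshold=2))
        assert len(state.qedge_bindings["e0"]) == 2

    def test_no_pinned_node_rejected(self, drug_protein_provider, hierarchy):
        qg = _qg(subject_cats=["Drug"], object_cats=["Protein"])
        with pytest.raises(ValueError, match="pinned"):
            expand(ReasoningState(query_graph=qg), [drug_protein_provider],
                   hierarchy, None, EngineConfig())

    def test_edges_bound_per_qedge_respect_threshold(self, bundle):
        from kgreason.querygraph import query_graph_from_dict

        qg = query_graph_from_dict(bundle.query_message["message"]["query_graph"])
        state = ReasoningState(query_graph=qg)
        expand(state, [bundle.provider()], bundle.hierarchy, None,
               EngineConfig(prune_threshold=3))
        for qedge_key in qg.edges:
            assert len(state.qedge_bindings[qedge_key]) <= 3

    def test_all_answer_nodes_reachable_from_pins(self, bundle):
        from kgreason.querygraph import query_graph_from_dict

        qg = query_graph_from_dict(bundle.query_message["message"]["query_graph"])
        state = ReasoningState(query_graph=qg)
        expand(state, [bundle.provider()], bundle.hierarchy, None, EngineConfig())
        # BFS over the answer KG from the pinned drug reaches everything
        pins = set(qg.pinned_ids()) & set(state.answer_kg.nodes)
        seen = set(pins)
        frontier = list(pins)
        while frontier:
            nid = frontier.pop()
            for nb in state.answer_kg.neighbors(nid):
                if nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        assert seen == set(state.answer_kg.nodes)

    def test_two_hop_query_builds_both_hops(self, bundle):
        qg = QueryGraph()
        qg.add_node(QueryNode("n0", ids=[bundle.manifest.pinned_drug_id]))
        qg.add_node(QueryNode("n1", categories=["Protein"]))
        qg.add_node(QueryNode("n2", categories=["Disease"]))
        qg.add_edge(QueryEdge("e0", "n0", "n1", predicates=["interacts_with"]))
        qg.add_edge(QueryEdge("e1", "n1", "n2", predicates=["associated_with"]))
        state = ReasoningState(query_graph=qg)
        expand(state, [bundle.provider()], bundle.hierarchy, None, EngineConfig())
        assert state.qedge_bindings["e0"] and state.qedge_bindings["e1"]
        assert bundle.manifest.hub_id in state.qnode_bindings["n2"]


class SlowProvider(GraphProvider):
    def __init__(self, inner: GraphProvider, delay: float):
        super().__init__("slow_kp", inner.graph, inner.hierarchy,
                         list(inner.meta_triples()))
        self.delay = delay

    def lookup(self, request):
        time.sleep(self.delay)
        return super().lookup(request)


class TestTimeoutContract:
    def test_slow_provider_abandoned_with_warning(
        self, drug_protein_provider, kg_factory, hierarchy
    ):
        other = GraphProvider(
            "fast_kp",
            kg_factory([("D:1", "Drug"), ("P:9", "Protein")],
                       [("f1", "D:1", "P:9", "interacts_with")]),
            hierarchy,
        )
        slow = SlowProvider(drug_protein_provider, delay=2.0)
        qg = _qg(subject_pin=["D:1"], object_cats=["Protein"])
        state = ReasoningState(query_graph=qg)
        expand(state, [slow, other], hierarchy, None,
               EngineConfig(kp_timeout=0.2))
        assert any("abandoned" in e.message for e in state.log if e.level == "WARNING")
        assert set(state.answer_kg.edges) == {"f1"}


class TestBatchEquivalence:
    def test_batched_lookup_equals_union_of_singles(self, kg_factory, hierarchy):
        kg = kg_factory(
            [("D:1", "Drug"), ("D:2", "Drug"), ("P:1", "Protein"), ("P:2", "Protein")],
            [
                ("e1", "D:1", "P:1", "interacts_with"),
                ("e2", "D:2", "P:2", "interacts_with"),
            ],
        )
        provider = GraphProvider("kp", kg, hierarchy)

        def req(ids):
            return LookupRequest(subject_ids=frozenset(ids),
                                 object_categories=frozenset({"Protein"}))

        from kgreason import merge_graphs

        batched = provider.lookup(req({"D:1", "D:2"}))
        union = merge_graphs([provider.lookup(req({"D:1"})),
                              provider.lookup(req({"D:2"}))])
        assert batched.same_content(union)


class TestPruneQedgeAnswers:
    def _planted_state(self, kg_factory):
        """Five pinned subjects (plus background proteins outside the pinned
        set, so connectivity to the pins is informative); candidate H connects
        to all five pins, candidates C1..C4 to one each."""
        nodes = [(f"S:{i}", "Protein") for i in range(5)]
        nodes += [(f"F:{i}", "Protein") for i in range(5)]
        nodes += [("H", "Disease")] + [(f"C:{i}", "Disease") for i in range(4)]
        edges = [(f"h{i}", f"S:{i}", "H", "associated_with") for i in range(5)]
        edges += [(f"c{i}", f"S:{i}", f"C:{i}", "associated_with") for i in range(4)]
        kg = kg_factory(nodes, edges)
        qg = QueryGraph()
        qg.add_node(QueryNode("n0", ids=[f"S:{i}" for i in range(5)]))
        qg.add_node(QueryNode("n1", categories=["Disease"]))
        qg.add_edge(QueryEdge("e0", "n0", "n1", predicates=["associated_with"]))
        state = ReasoningState(query_graph=qg, answer_kg=kg.copy())
        state.qnode_bindings["n0"] = {f"S:{i}" for i in range(5)}
        state.qnode_bindings["n1"] = {"H"} | {f"C:{i}" for i in range(4)}
        state.qedge_bindings["e0"] = set(kg.edges)
        return kg, state

    def test_under_threshold_is_noop(self, kg_factory):
        kg, state = self._planted_state(kg_factory)
        before = set(state.qedge_bindings["e0"])
        prune_qedge_answers(state, "e0", threshold=100, background=kg)
        assert state.qedge_bindings["e0"] == before

    def test_fully_connected_candidate_retained_first(self, kg_factory):
        kg, state = self._planted_state(kg_factory)
        prune_qedge_answers(state, "e0", threshold=5, background=kg)
        assert state.qnode_bindings["n1"] == {"H"}
        assert state.qedge_bindings["e0"] == {f"h{i}" for i in range(5)}
        assert "C:0" not in state.answer_kg.nodes

    def test_equal_scores_keep_lexicographically_smallest(self, kg_factory):
        kg, state = self._planted_state(kg_factory)
        # drop the hub so all four remaining candidates tie at one edge each
        state.qedge_bindings["e0"] -= {f"h{i}" for i in range(5)}
        state.qnode_bindings["n1"].discard("H")
        prune_qedge_answers(state, "e0", threshold=2, background=kg)
        assert state.qnode_bindings["n1"] == {"C:0", "C:1"}
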