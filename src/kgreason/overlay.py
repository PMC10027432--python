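"""Statistical overlays: virtual edges carrying contextual evidence.

Overlays annotate an answer KG with *virtual* edges — edges that fulfill no
query edge of the original question but carry quantitative context used
later for filtering and ranking:

* **Fisher exact enrichment** — how non-random the one-hop connectivity is
  between the nodes bound to a subject query node and each candidate object
  node, measured against a background graph (the local knowledge corpus).
* **Jaccard-style neighbor sharing** — the fraction of a start node's
  intermediate-category neighbors that are also adjacent to an end node,
  JS(v_s, v_e) = n / Deg(v_s).
* **Normalized co-occurrence distance (NGD)** — a log-ratio statistic over a
  literature co-occurrence index; 0 means the two terms always co-occur,
  larger values mean weaker association.
* **Pluggable predictors** — e.g. a drug-treats-disease link-prediction
  model, exposed behind a callable contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Optional, Set, Tuple

from scipy import stats

from .graph import Attribute, KnowledgeEdge, KnowledgeGraph
from .state import ReasoningState

logger = logging.getLogger(__name__)

#: Sentinel for statistics that are undefined on the given inputs.
MISSING = float("nan")

OVERLAY_KINDS = ("fisher", "jaccard", "ngd", "predictor")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows = connected / not connected to the object node,
    columns = in the subject set / not in the subject set."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is all zero")


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table.

    The two-sided p sums hypergeometric point probabilities, over all tables
    with the observed margins, that do not exceed the observed table's point
    probability (standard two-sided convention).
    """
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(min(p, 1.0))


@dataclass
class CooccurrenceIndex:
    """Term and term-pair occurrence counts over an annotated corpus."""

    occurrence: Dict[str, int] = field(default_factory=dict)
    pair: Dict[FrozenSet[str], int] = field(default_factory=dict)
    total: int = 0

    def add_term(self, term: str, count: int) -> None:
        self.occurrence[term] = count

    def add_pair(self, t1: str, t2: str, count: int) -> None:
        self.pair[frozenset((t1, t2))] = count

    def pair_count(self, t1: str, t2: str) -> int:
        return self.pair.get(frozenset((t1, t2)), 0)

    def validate(self) -> None:
        for key, c in self.pair.items():
            pair = sorted(key)
            t1, t2 = (pair[0], pair[-1])
            lo = min(self.occurrence.get(t1, 0), self.occurrence.get(t2, 0))
            if c > lo:
                raise ValueError(f"pair count for {t1}/{t2} exceeds a term count")
        if any(c > self.total for c in self.occurrence.values()):
            raise ValueError("term count exceeds corpus total")


def normalized_cooccurrence_distance(
    t1: str, t2: str, index: CooccurrenceIndex
) -> float:
    """NGD(t1, t2) = [max(log f1, log f2) - log f12] / [log N - min(log f1, log f2)].

    Base-invariant (a ratio of log differences).  Returns the missing
    sentinel (NaN) when either term is absent from the index, any count is
    zero, or the pair never co-occurs.
    """
    if t1 not in index.occurrence or t2 not in index.occurrence:
        logger.warning("term absent from co-occurrence index: %r / %r", t1, t2)
        return MISSING
    f1 = index.occurrence[t1]
    f2 = index.occurrence[t2]
    f12 = index.pair_count(t1, t2)
    if f1 == 0 or f2 == 0 or f12 == 0 or index.total <= 0:
        return MISSING
    lf1, lf2, lf12, ln = (math.log(f1), math.log(f2), math.log(f12), math.log(index.total))
    denom = ln - min(lf1, lf2)
    if denom <= 0:
        return MISSING
    return (max(lf1, lf2) - lf12) / denom


def jaccard_similarity(
    background: KnowledgeGraph,
    v_s: str,
    v_e: str,
    intermediate_category: str,
    hierarchy,
) -> float:
    """Shared-intermediate-neighbor fraction n / Deg(v_s).

    Deg(v_s) counts distinct neighbors of ``v_s`` (direction and edge
    multiplicity ignored) belonging to ``intermediate_category`` after
    hierarchy expansion; n counts those also adjacent to ``v_e``.  Returns
    the missing sentinel when ``v_s`` has no qualifying neighbors.
    """
    from .hierarchy import term_matches

    for v in (v_s, v_e):
        if v not in background.nodes:
            raise KeyError(f"unknown node {v!r}")
    intermediates = {
        nb
        for nb in background.neighbors(v_s)
        if any(
            term_matches(hierarchy, c, [intermediate_category])
            for c in background.nodes[nb].categories
        )
    }
    if not intermediates:
        return MISSING
    shared = intermediates & background.neighbors(v_e)
    return len(shared) / len(intermediates)


def _subject_population(
    background: KnowledgeGraph, subject_ids: Set[str], v_o: str
) -> Set[str]:
    """Background nodes comparable to the subject set: everything sharing a
    category with some subject node, minus the object node itself."""
    cats: Set[str] = set()
    for s in subject_ids:
        node = background.nodes.get(s)
        if node is not None:
            cats |= node.categories
    pop = {
        nid
        for nid, node in background.nodes.items()
        if node.categories & cats and nid != v_o
    }
    return pop | (subject_ids - {v_o})


def fisher_enrichment_pvalues(
    background: KnowledgeGraph, subject_ids: Set[str], object_ids: Set[str]
) -> Dict[str, Tuple[float, Set[str]]]:
    """For each candidate object node, the Fisher exact p-value of its
    connectivity to the subject set, plus the subjects it connects to.

    The population classified into the table is the set of background nodes
    sharing a category with the subject binding; rows split it by adjacency
    to the object candidate, columns by membership in the subject set.
    """
    out: Dict[str, Tuple[float, Set[str]]] = {}
    for v_o in sorted(object_ids):
        if v_o not in background.nodes:
            continue
        pop = _subject_population(background, subject_ids, v_o)
        connected = background.neighbors(v_o) & pop
        in_s = subject_ids & pop
        a = len(connected & in_s)
        b = len(connected - in_s)
        c = len(in_s - connected)
        d = len(pop - connected - in_s)
        if a + b + c + d == 0:
            continue
        p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        out[v_o] = (p, connected & in_s)
    return out


def _attach_virtual_edge(
    state: ReasoningState,
    qedge_key: str,
    subject: str,
    obj: str,
    predicate: str,
    attribute: Attribute,
) -> None:
    eid = f"virtual:{qedge_key}:{subject}--{obj}:{attribute.name}"
    state.answer_kg.add_edge(
        KnowledgeEdge(
            id=eid,
            subject=subject,
            object=obj,
            predicate=predicate,
            primary_source="overlay",
            is_virtual=True,
            qedge_key=qedge_key,
            attributes=[attribute],
        )
    )
    state.qedge_bindings.setdefault(qedge_key, set()).add(eid)


def overlay_fisher(
    state: ReasoningState,
    subject_qnode_key: str,
    object_qnode_key: str,
    background: KnowledgeGraph,
    predicate: str = "related_to",
) -> ReasoningState:
    """Attach Fisher-enrichment virtual edges from connected subjects to each
    object candidate, carrying the candidate's ``fisher_exact_p``."""
    subjects = set(state.qnode_bindings.get(subject_qnode_key, set()))
    objects = set(state.qnode_bindings.get(object_qnode_key, set()))
    if not subjects or not objects:
        state.warning(
            f"overlay fisher: empty binding for {subject_qnode_key!r} or "
            f"{object_qnode_key!r}; nothing to do"
        )
        return state
    pvalues = fisher_enrichment_pvalues(background, subjects, objects)
    qedge_key = state.next_virtual_key()
    n_edges = 0
    for v_o, (p, connected_subjects) in sorted(pvalues.items()):
        for v_s in sorted(connected_subjects):
            _attach_virtual_edge(
                state,
                qedge_key,
                v_s,
                v_o,
                predicate,
                Attribute("fisher_exact_p", p, source="overlay_fisher"),
            )
            n_edges += 1
    state.info(
        f"overlay fisher: {n_edges} virtual edges under qedge key {qedge_key!r}"
    )
    return state


def overlay_virtual_edges(
    state: ReasoningState,
    kind: str,
    *,
    subject_qnode_key: str,
    object_qnode_key: str,
    background: Optional[KnowledgeGraph] = None,
    hierarchy=None,
    intermediate_category: Optional[str] = None,
    cooccurrence_index: Optional[CooccurrenceIndex] = None,
    predictor: Optional[Callable[[str, str], float]] = None,
    predictor_attribute: str = "probability_treats",
) -> ReasoningState:
    """Compute the named statistic for every bound (subject, object) pair and
    attach virtual edges under a fresh query-edge key (v0, v1, ...)."""
    if kind not in OVERLAY_KINDS:
        raise ValueError(f"unknown overlay kind {kind!r}; expected one of {OVERLAY_KINDS}")
    if kind == "fisher":
        if background is None:
            raise ValueError("fisher overlay requires a background graph")
        return overlay_fisher(state, subject_qnode_key, object_qnode_key, background)

    subjects = sorted(state.qnode_bindings.get(subject_qnode_key, set()))
    objects = sorted(state.qnode_bindings.get(object_qnode_key, set()))
    if not subjects or not objects:
        state.warning(f"overlay {kind}: empty binding; nothing to do")
        return state

    qedge_key = state.next_virtual_key()
    n_edges = 0
    for v_s in subjects:
        for v_o in objects:
            if v_s == v_o:
                continue
            if kind == "jaccard":
                if background is None or hierarchy is None or intermediate_category is None:
                    raise ValueError(
                        "jaccard overlay requires background, hierarchy and"
                        " intermediate_category"
                    )
                value = jaccard_similarity(
                    background, v_s, v_o, intermediate_category, hierarchy
                )
                attr_name = "jaccard_index"
            elif kind == "ngd":
                if cooccurrence_index is None:
                    raise ValueError("ngd overlay requires a co-occurrence index")
                t1 = state.answer_kg.nodes[v_s].name
                t2 = state.answer_kg.nodes[v_o].name
                value = normalized_cooccurrence_distance(t1, t2, cooccurrence_index)
                attr_name = "ngd"
            else:  # predictor
                if predictor is None:
                    raise ValueError("predictor overlay requires a predictor handle")
                value = float(predictor(v_s, v_o))
                attr_name = predictor_attribute
            if isinstance(value, float) and math.isnan(value):
                continue
            _attach_virtual_edge(
                state,
                qedge_key,
                v_s,
                v_o,
                "related_to",
                Attribute(attr_name, value, source=f"overlay_{kind}"),
            )
            n_edges += 1
    state.info(f"overlay {kind}: {n_edges} virtual edges under qedge key {qedge_key!r}")
    return state


def constant_predictor(value: float) -> Callable[[str, str], float]:
    """A deterministic stand-in for a trained link-prediction model."""

    def predict(subject: str, obj: str) -> float:
        return value

    return predict
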