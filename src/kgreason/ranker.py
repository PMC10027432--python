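"""Result scoring and ranking.

Each result subgraph is scored in three stages: (1) every edge gets a
confidence in [0, 1] by normalizing its scalar attributes through
attribute-specific sigmoids and its supporting-publication count through the
calibrated transform 1 / (1 + (b/n)^a) with a = log2(9) and b = 4, so that
4 publications score 0.5 and 8 score 0.9; (2) three whole-graph weights are
computed on the result's bound subgraph using those edge confidences —
maximum flow between terminal nodes, the Frobenius norm of the edge-weight
vector, and the weight of the longest minimum-hop (geodesic) path between
terminals; (3) results are fractionally ranked on each metric separately and
the final score is the mean rank normalized to [0, 1].
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
from scipy import stats

from .graph import KnowledgeEdge, KnowledgeGraph
from .querygraph import QueryGraph

if TYPE_CHECKING:  # pragma: no cover
    from .resultify import Result

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SigmoidSpec:
    """Logistic normalizer for one attribute type.

    ``transform`` optionally maps the raw value first ("neglog10" for
    p-values, "identity" otherwise). ``midpoint`` is the transformed value
    scoring 0.5, ``steepness`` the transformed-scale width of the transition,
    and ``ascending`` whether larger transformed values score higher.
    """

    midpoint: float
    steepness: float = 1.0
    ascending: bool = True
    transform: str = "identity"
    weight: float = 1.0

    def __post_init__(self):
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def score(self, value: float) -> float:
        x = value
        if self.transform == "neglog10":
            x = -math.log10(max(value, 1e-300))
        elif self.transform == "clip01":
            return min(max(value, 0.0), 1.0) ** self.weight
        z = (x - self.midpoint) / self.steepness
        if not self.ascending:
            z = -z
        return (1.0 / (1.0 + math.exp(-z))) ** self.weight


def _default_sigmoids() -> Dict[str, SigmoidSpec]:
    return {
        # scored on -log10(p); p = 1e-5 sits at the midpoint, one decade wide
        "fisher_exact_p": SigmoidSpec(midpoint=5.0, steepness=1.0, transform="neglog10"),
        # larger co-occurrence distance = weaker association
        "ngd": SigmoidSpec(midpoint=0.6, steepness=0.1, ascending=False),
        "jaccard_index": SigmoidSpec(midpoint=0.0, transform="clip01"),
        "probability_treats": SigmoidSpec(midpoint=0.0, transform="clip01"),
    }


@dataclass
class RankerConfig:
    publication_a: float = math.log2(9)
    publication_b: float = 4.0
    sigmoids: Dict[str, SigmoidSpec] = field(default_factory=_default_sigmoids)
    base_edge_score: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.base_edge_score <= 1.0:
            raise ValueError("base_edge_score must be in [0, 1]")


@dataclass(frozen=True)
class GraphMetrics:
    max_flow: float
    frobenius: float
    longest_geodesic_weight: float

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.max_flow, self.frobenius, self.longest_geodesic_weight)


def publication_count_score(n: int, config: Optional[RankerConfig] = None) -> float:
    """Confidence contributed by ``n`` supporting publications.

    1 / (1 + (b/n)^a) with defaults a = log2(9), b = 4: strictly increasing,
    0 at n = 0, 0.5 at n = 4, 0.9 at n = 8, limit 1 as n grows.
    """
    if n < 0:
        raise ValueError("publication count must be non-negative")
    if n == 0:
        return 0.0
    cfg = config or RankerConfig()
    return 1.0 / (1.0 + (cfg.publication_b / n) ** cfg.publication_a)


def attribute_to_unit_score(
    value: float, attribute_name: str, config: Optional[RankerConfig] = None
) -> float:
    """Normalize one scalar edge attribute to [0, 1].

    Attribute names without a configured sigmoid fall back to the base edge
    score (no information either way).
    """
    cfg = config or RankerConfig()
    spec = cfg.sigmoids.get(attribute_name)
    if spec is None:
        return cfg.base_edge_score
    return spec.score(float(value))


def _publication_count(edge: KnowledgeEdge) -> Optional[int]:
    attr = edge.get_attribute("publications")
    if attr is None:
        return None
    v = attr.value
    if isinstance(v, (int, float)):
        return int(v)
    if isinstance(v, str):
        return 1 if v else 0
    return len(list(v))


def edge_confidence(
    edge: KnowledgeEdge, config: Optional[RankerConfig] = None
) -> float:
    """Product of unit scores of the edge's recognized scalar attributes,
    times the publication-count score when publications are listed; an edge
    with nothing recognized gets the base score."""
    cfg = config or RankerConfig()
    score = 1.0
    informative = False
    for attr in edge.attributes:
        spec = cfg.sigmoids.get(attr.name)
        if spec is not None and isinstance(attr.value, (int, float)):
            score *= spec.score(float(attr.value))
            informative = True
    n_pubs = _publication_count(edge)
    if n_pubs is not None:
        score *= publication_count_score(n_pubs, cfg)
        informative = True
    return score if informative else cfg.base_edge_score


def _terminal_nodes(result: "Result", qg: QueryGraph) -> List[str]:
    """Flow/geodesic endpoints: nodes bound to degree-1 query nodes; if the
    query has fewer than two such (e.g. cycles), all bound nodes qualify."""
    terminals = sorted(
        {
            result.node_bindings[k]
            for k in qg.nodes
            if qg.qnode_degree(k) == 1 and k in result.node_bindings
        }
    )
    if len(terminals) < 2:
        terminals = sorted(set(result.node_bindings.values()))
    return terminals


def _bound_weighted_graph(
    result: "Result", kg: KnowledgeGraph, config: RankerConfig
) -> nx.Graph:
    """Simple undirected graph over the result's bound nodes; parallel-edge
    confidences are summed into a single weight per node pair."""
    g = nx.Graph()
    g.add_nodes_from(sorted(set(result.node_bindings.values())))
    for eids in result.edge_bindings.values():
        for eid in sorted(eids):
            edge = kg.edges[eid]
            w = edge_confidence(edge, config)
            if g.has_edge(edge.subject, edge.object):
                g[edge.subject][edge.object]["weight"] += w
            else:
                g.add_edge(edge.subject, edge.object, weight=w)
    return g


def result_graph_metrics(
    result: "Result",
    kg: KnowledgeGraph,
    qg: QueryGraph,
    config: Optional[RankerConfig] = None,
) -> GraphMetrics:
    """Max-flow, Frobenius norm and longest-geodesic weight of the result's
    bound subgraph under edge-confidence weights."""
    cfg = config or RankerConfig()
    g = _bound_weighted_graph(result, kg, cfg)

    frobenius = math.sqrt(
        sum(d["weight"] ** 2 for _, _, d in g.edges(data=True))
    )

    terminals = _terminal_nodes(result, qg)
    max_flow = 0.0
    longest_geo = 0.0
    if len(terminals) >= 2 and g.number_of_edges() > 0:
        for s, t in itertools.combinations(terminals, 2):
            if s not in g or t not in g or not nx.has_path(g, s, t):
                logger.info("terminals %s and %s disconnected in bound subgraph", s, t)
                continue
            flow = nx.maximum_flow_value(g, s, t, capacity="weight")
            max_flow = max(max_flow, flow)
            # minimum-hop paths; tie broken by maximum total weight
            best = 0.0
            for path in nx.all_shortest_paths(g, s, t):
                w = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
                best = max(best, w)
            longest_geo = max(longest_geo, best)
    return GraphMetrics(max_flow, frobenius, longest_geo)


def score_results(
    results: Sequence["Result"],
    kg: KnowledgeGraph,
    qg: QueryGraph,
    config: Optional[RankerConfig] = None,
) -> List["Result"]:
    """Attach final scores by rank aggregation and sort descending.

    Each of the three graph metrics is ranked over the results with
    fractional (mean-of-ties) descending ranks; a result's score is
    (N - mean_rank) / (N - 1), so the uniformly best result scores 1 and the
    uniformly worst scores 0.  A single result scores 1.0.  Ties in final
    score order by ascending node-binding signature.
    """
    if not results:
        return []
    cfg = config or RankerConfig()
    metrics = [result_graph_metrics(r, kg, qg, cfg) for r in results]
    n = len(results)
    if n == 1:
        results[0].score = 1.0
        return list(results)
    mean_ranks = [0.0] * n
    for dim in range(3):
        vals = [m.as_tuple()[dim] for m in metrics]
        # rankdata ranks ascending; negate for descending-rank semantics
        ranks = stats.rankdata([-v for v in vals], method="average")
        for i, r in enumerate(ranks):
            mean_ranks[i] += r / 3.0
    for res, rbar in zip(results, mean_ranks):
        res.score = float((n - rbar) / (n - 1))
    return sorted(
        results,
        key=lambda r: (-r.score, sorted(r.node_bindings.items())),
    )
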