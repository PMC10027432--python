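"""The workflow command language: parsing, templating and execution.

Analysis workflows are ordered command sequences over a small vocabulary —
``add_qnode``/``add_qedge`` build the query graph incrementally, ``expand``
retrieves and prunes answers from knowledge providers, ``overlay`` annotates
the answer KG with statistical virtual edges, ``filter_kg``/``filter_results``
trim it, ``resultify`` enumerates fulfilling subgraphs and ``rank_results``
scores them.  A bare query graph is translated into a workflow by a
deterministic template; a workflow script is one command per line, written
``name(key=value, key=[v1,v2])`` with ``#`` comments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Union

from .filtering import filter_kg, filter_results
from .graph import KnowledgeGraph, merge_graphs
from .hierarchy import OntologyHierarchy
from .overlay import CooccurrenceIndex, overlay_virtual_edges
from .providers import EngineConfig, KnowledgeProvider
from .querygraph import QueryEdge, QueryGraph, QueryNode
from .ranker import RankerConfig, score_results
from .resultify import resultify
from .state import ReasoningState
from .synonymizer import Synonymizer

Scalar = Union[int, float, bool, str]
ParamValue = Union[Scalar, List[Scalar]]

COMMAND_NAMES = (
    "add_qnode",
    "add_qedge",
    "expand",
    "overlay",
    "filter_kg",
    "filter_results",
    "resultify",
    "rank_results",
)

_COMMAND_PARAMS: Dict[str, set] = {
    "add_qnode": {"key", "ids", "categories"},
    "add_qedge": {"key", "subject", "object", "predicates"},
    "expand": {"prune_threshold", "kp_timeout"},
    "overlay": {
        "action",
        "subject_qnode_key",
        "object_qnode_key",
        "intermediate_category",
        "predictor",
    },
    "filter_kg": {"target", "attribute_name", "direction", "threshold", "remove_orphans"},
    "filter_results": {"sort_by", "ascending", "limit"},
    "resultify": {"ignore_edge_direction", "strict_injective"},
    "rank_results": set(),
}

# TRAPI-operations vocabulary accepted as thin aliases onto native commands
_OPERATION_ALIASES: Dict[str, str] = {
    "lookup": "expand",
    "overlay_compute_ngd": "overlay",
    "overlay_compute_jaccard": "overlay",
    "overlay_fisher_exact_test": "overlay",
    "filter_kgraph": "filter_kg",
    "filter_results_top_n": "filter_results",
    "sort_results_score": "filter_results",
    "complete_results": "resultify",
    "score": "rank_results",
}


class WorkflowSyntaxError(ValueError):
    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class Command:
    name: str
    params: tuple  # sorted tuple of (key, value) pairs; lists stored as tuples

    @staticmethod
    def make(name: str, params: Optional[Dict[str, ParamValue]] = None) -> "Command":
        if name not in COMMAND_NAMES:
            raise ValueError(f"unknown command {name!r}")
        params = params or {}
        allowed = _COMMAND_PARAMS[name]
        for k in params:
            if k not in allowed:
                raise ValueError(f"command {name!r} does not accept parameter {k!r}")
        frozen = tuple(
            sorted(
                (k, tuple(v) if isinstance(v, list) else v) for k, v in params.items()
            )
        )
        return Command(name, frozen)

    def get(self, key: str, default=None):
        for k, v in self.params:
            if k == key:
                return list(v) if isinstance(v, tuple) else v
        return default

    def param_dict(self) -> Dict[str, ParamValue]:
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.params}


@dataclass
class Workflow:
    commands: List[Command] = field(default_factory=list)

    def __post_init__(self):
        if not isinstance(self.commands, list):
            self.commands = list(self.commands)

    def __iter__(self):
        return iter(self.commands)

    def __len__(self):
        return len(self.commands)

    def __eq__(self, other):
        return isinstance(other, Workflow) and self.commands == other.commands


_LINE_RE = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_]*)\s*\((.*)\)\s*$")
_INT_RE = re.compile(r"^[+-]?\d+$")
_FLOAT_RE = re.compile(r"^[+-]?(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?$")


def _parse_scalar(token: str) -> Scalar:
    token = token.strip()
    if _INT_RE.match(token):
        return int(token)
    if _FLOAT_RE.match(token) and ("." in token or "e" in token or "E" in token):
        return float(token)
    if token == "true":
        return True
    if token == "false":
        return False
    return token


def _split_args(body: str, line_number: int) -> List[str]:
    args, depth, current = [], 0, []
    for ch in body:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise WorkflowSyntaxError(line_number, "unbalanced ']'")
        if ch == "," and depth == 0:
            args.append("".join(current))
            current = []
        else:
            current.append(ch)
    if depth != 0:
        raise WorkflowSyntaxError(line_number, "unbalanced '['")
    if current:
        args.append("".join(current))
    return [a for a in (s.strip() for s in args) if a]


def parse_workflow(script: Union[str, Sequence[str]]) -> Workflow:
    """Parse a workflow script (one command per line) into a Workflow.

    Values are parsed as integers, floats, booleans (``true``/``false``),
    bracketed sequences, or bare text/CURIE tokens.  Unknown command names or
    parameters are rejected with the offending line number.
    """
    if isinstance(script, str):
        lines = script.splitlines()
    else:
        lines = list(script)
    commands: List[Command] = []
    for i, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _LINE_RE.match(line)
        if not m:
            raise WorkflowSyntaxError(i, f"expected name(...), got {line!r}")
        name, body = m.group(1), m.group(2)
        if name not in COMMAND_NAMES:
            raise WorkflowSyntaxError(i, f"unknown command {name!r}")
        params: Dict[str, ParamValue] = {}
        for arg in _split_args(body, i):
            if "=" not in arg:
                raise WorkflowSyntaxError(i, f"expected key=value, got {arg!r}")
            key, value = arg.split("=", 1)
            key, value = key.strip(), value.strip()
            if value.startswith("[") and value.endswith("]"):
                inner = value[1:-1].strip()
                parsed: ParamValue = (
                    [_parse_scalar(t) for t in inner.split(",") if t.strip()]
                    if inner
                    else []
                )
            else:
                parsed = _parse_scalar(value)
            params[key] = parsed
        try:
            commands.append(Command.make(name, params))
        except ValueError as exc:
            raise WorkflowSyntaxError(i, str(exc)) from exc
    return Workflow(commands)


def _render_value(value: ParamValue) -> str:
    if isinstance(value, list):
        return "[" + ",".join(_render_value(v) for v in value) + "]"
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def render_workflow(wf: Workflow) -> str:
    """Serialize a Workflow back to script text (parse/render round-trips)."""
    lines = []
    for cmd in wf:
        body = ", ".join(f"{k}={_render_value(v)}" for k, v in cmd.param_dict().items())
        lines.append(f"{cmd.name}({body})")
    return "\n".join(lines)


def interpret_query_graph(qg: QueryGraph) -> Workflow:
    """Translate a bare query graph into the universal workflow template:
    reconstruct the query graph, then expand, resultify and rank."""
    qg.validate()
    commands: List[Command] = []
    for key in sorted(qg.nodes):
        n = qg.nodes[key]
        params: Dict[str, ParamValue] = {"key": key}
        if n.ids:
            params["ids"] = list(n.ids)
        if n.categories:
            params["categories"] = list(n.categories)
        commands.append(Command.make("add_qnode", params))
    for key in sorted(qg.edges):
        e = qg.edges[key]
        params = {"key": key, "subject": e.subject_key, "object": e.object_key}
        if e.predicates:
            params["predicates"] = list(e.predicates)
        commands.append(Command.make("add_qedge", params))
    commands.append(Command.make("expand"))
    commands.append(Command.make("resultify"))
    commands.append(Command.make("rank_results"))
    return Workflow(commands)


def operations_to_workflow(operations: Sequence[dict]) -> Workflow:
    """Accept the standardized operations vocabulary as aliases onto native
    commands; unsupported operation ids are rejected."""
    commands = []
    for op in operations:
        op_id = op.get("id")
        if op_id not in _OPERATION_ALIASES:
            raise ValueError(
                f"unsupported operation {op_id!r}; supported: "
                f"{sorted(_OPERATION_ALIASES)}"
            )
        name = _OPERATION_ALIASES[op_id]
        params = dict(op.get("parameters") or {})
        if op_id == "overlay_compute_ngd":
            params.setdefault("action", "ngd")
        elif op_id == "overlay_compute_jaccard":
            params.setdefault("action", "jaccard")
        elif op_id == "overlay_fisher_exact_test":
            params.setdefault("action", "fisher")
        elif op_id == "sort_results_score":
            params.setdefault("sort_by", "score")
        commands.append(Command.make(name, params))
    return Workflow(commands)


class CommandError(RuntimeError):
    pass


def execute_workflow(
    wf: Workflow,
    providers: Sequence[KnowledgeProvider],
    config: EngineConfig,
    *,
    hierarchy: OntologyHierarchy,
    synonymizer: Optional[Synonymizer] = None,
    cooccurrence_index: Optional[CooccurrenceIndex] = None,
    predictor: Optional[Callable[[str, str], float]] = None,
    ranker_config: Optional[RankerConfig] = None,
    state: Optional[ReasoningState] = None,
) -> ReasoningState:
    """Dispatch commands in order, threading the reasoning state through.

    Every command appends log entries; on failure the error is logged and
    execution halts, returning the partial state.
    """
    from .expander import expand as run_expand
    from .synonymizer import canonicalize_graph

    if not len(wf):
        raise ValueError("workflow is empty")
    st = state or ReasoningState()
    rcfg = ranker_config or RankerConfig(base_edge_score=config.base_edge_score)

    background: Optional[KnowledgeGraph] = None

    def get_background() -> KnowledgeGraph:
        nonlocal background
        if background is None:
            background = merge_graphs(
                [p.graph for p in providers if hasattr(p, "graph")]
            )
            if synonymizer is not None:
                background = canonicalize_graph(background, synonymizer)
        return background

    for idx, cmd in enumerate(wf):
        try:
            st.info(f"executing {cmd.name}")
            if cmd.name == "add_qnode":
                key = cmd.get("key")
                if not key:
                    raise CommandError("add_qnode requires key")
                st.query_graph.add_node(
                    QueryNode(
                        key=key,
                        ids=cmd.get("ids"),
                        categories=cmd.get("categories"),
                    )
                )
            elif cmd.name == "add_qedge":
                key = cmd.get("key")
                if not key or not cmd.get("subject") or not cmd.get("object"):
                    raise CommandError("add_qedge requires key, subject and object")
                st.query_graph.add_edge(
                    QueryEdge(
                        key=key,
                        subject_key=cmd.get("subject"),
                        object_key=cmd.get("object"),
                        predicates=cmd.get("predicates"),
                    )
                )
            elif cmd.name == "expand":
                cfg = config
                override = cmd.get("prune_threshold")
                timeout = cmd.get("kp_timeout")
                if override is not None or timeout is not None:
                    cfg = EngineConfig(
                        prune_threshold=(
                            int(override) if override is not None else config.prune_threshold
                        ),
                        kp_timeout=(
                            float(timeout) if timeout is not None else config.kp_timeout
                        ),
                        prevalent_categories=config.prevalent_categories,
                        seed=config.seed,
                        base_edge_score=config.base_edge_score,
                    )
                run_expand(st, providers, hierarchy, synonymizer, cfg)
            elif cmd.name == "overlay":
                action = cmd.get("action")
                if action is None:
                    raise CommandError("overlay requires action")
                overlay_virtual_edges(
                    st,
                    action,
                    subject_qnode_key=cmd.get("subject_qnode_key"),
                    object_qnode_key=cmd.get("object_qnode_key"),
                    background=get_background(),
                    hierarchy=hierarchy,
                    intermediate_category=cmd.get("intermediate_category"),
                    cooccurrence_index=cooccurrence_index,
                    predictor=predictor,
                )
            elif cmd.name == "filter_kg":
                filter_kg(
                    st,
                    target=cmd.get("target"),
                    attribute_name=cmd.get("attribute_name"),
                    direction=cmd.get("direction"),
                    threshold=float(cmd.get("threshold")),
                    remove_orphans=bool(cmd.get("remove_orphans", False)),
                )
            elif cmd.name == "filter_results":
                filter_results(
                    st,
                    sort_by=cmd.get("sort_by", "score"),
                    ascending=bool(cmd.get("ascending", False)),
                    limit=int(cmd.get("limit", 0)),
                )
            elif cmd.name == "resultify":
                resultify(
                    st,
                    hierarchy,
                    ignore_edge_direction=bool(cmd.get("ignore_edge_direction", True)),
                    strict_injective=bool(cmd.get("strict_injective", False)),
                )
            elif cmd.name == "rank_results":
                st.results = score_results(
                    st.results, st.answer_kg, st.query_graph, rcfg
                )
                st.ranked = True
                st.info(f"ranked {len(st.results)} results")
            else:  # pragma: no cover - Command.make guards the vocabulary
                raise CommandError(f"unhandled command {cmd.name!r}")
        except Exception as exc:
            st.error(f"command {idx + 1} ({cmd.name}) failed: {exc}")
            break
    return st
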