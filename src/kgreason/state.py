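"""Mutable reasoning state threaded through a workflow execution."""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, List, Set

from .graph import KnowledgeGraph
from .querygraph import QueryGraph

if TYPE_CHECKING:  # pragma: no cover
    from .resultify import Result


@dataclass
class LogEntry:
    level: str
    message: str
    timestamp: float = field(default_factory=time.time)

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "message": self.message,
            "timestamp": self.timestamp,
        }


@dataclass
class ReasoningState:
    query_graph: QueryGraph = field(default_factory=QueryGraph)
    answer_kg: KnowledgeGraph = field(default_factory=KnowledgeGraph)
    results: List["Result"] = field(default_factory=list)
    log: List[LogEntry] = field(default_factory=list)
    # bookkeeping maintained by the expander: which KG nodes/edges fulfill
    # which query nodes/edges
    qnode_bindings: Dict[str, Set[str]] = field(default_factory=dict)
    qedge_bindings: Dict[str, Set[str]] = field(default_factory=dict)
    virtual_qedge_count: int = 0
    ranked: bool = False

    def info(self, message: str) -> None:
        self.log.append(LogEntry("INFO", message))

    def warning(self, message: str) -> None:
        self.log.append(LogEntry("WARNING", message))

    def error(self, message: str) -> None:
        self.log.append(LogEntry("ERROR", message))

    def next_virtual_key(self) -> str:
        key = f"v{self.virtual_qedge_count}"
        self.virtual_qedge_count += 1
        return key
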