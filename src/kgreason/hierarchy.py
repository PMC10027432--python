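"""Category / predicate hierarchies and descendant-aware term matching.

Biomedical semantic layers (e.g. the Biolink model) organise node categories
and edge predicates into hierarchies: a query constraint such as
``interacts_with`` is fulfilled by any descendant predicate such as
``physically_interacts_with``.  This module holds the two hierarchies
(categories and predicates, disjoint namespaces) as parent-link DAGs and
answers reflexive-transitive descendant queries against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Set

CATEGORY = "category"
PREDICATE = "predicate"
_NAMESPACES = (CATEGORY, PREDICATE)


class UnknownTermError(KeyError):
    """Raised when a term is absent from the requested namespace."""

    def __init__(self, term: str, namespace: str):
        super().__init__(f"unknown {namespace} term: {term!r}")
        self.term = term
        self.namespace = namespace


@dataclass
class OntologyHierarchy:
    """Two parent-link DAGs: one for categories, one for predicates.

    ``parents[namespace][term]`` is the (possibly empty) set of parents; a
    root has no parents.  Multiple parents are allowed (mixin-style DAGs),
    so descendant computation is graph reachability, not a tree walk.
    """

    parents: Dict[str, Dict[str, Set[str]]] = field(
        default_factory=lambda: {CATEGORY: {}, PREDICATE: {}}
    )
    roots: Dict[str, str] = field(default_factory=dict)

    # children maps are derived lazily and cached
    _children: Dict[str, Dict[str, Set[str]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def add_term(self, namespace: str, term: str, parents: Iterable[str] = ()) -> None:
        if namespace not in _NAMESPACES:
            raise ValueError(f"namespace must be one of {_NAMESPACES}, got {namespace!r}")
        ns = self.parents[namespace]
        entry = ns.setdefault(term, set())
        for p in parents:
            ns.setdefault(p, set())
            entry.add(p)
        if not entry and namespace not in self.roots:
            self.roots[namespace] = term
        self._children.pop(namespace, None)

    def namespace_of(self, term: str) -> str:
        for ns in _NAMESPACES:
            if term in self.parents[ns]:
                return ns
        raise UnknownTermError(term, "category-or-predicate")

    def has_term(self, namespace: str, term: str) -> bool:
        return term in self.parents[namespace]

    def root(self, namespace: str) -> str:
        return self.roots[namespace]

    def _children_map(self, namespace: str) -> Dict[str, Set[str]]:
        cached = self._children.get(namespace)
        if cached is None:
            cached = {t: set() for t in self.parents[namespace]}
            for child, ps in self.parents[namespace].items():
                for p in ps:
                    cached.setdefault(p, set()).add(child)
            self._children[namespace] = cached
        return cached

    def descendants(self, namespace: str, term: str) -> FrozenSet[str]:
        """Reflexive-transitive descendants of ``term`` within ``namespace``."""
        if term not in self.parents[namespace]:
            raise UnknownTermError(term, namespace)
        children = self._children_map(namespace)
        seen = {term}
        stack = [term]
        while stack:
            for c in children.get(stack.pop(), ()):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return frozenset(seen)

    def ancestors(self, namespace: str, term: str) -> FrozenSet[str]:
        """Reflexive-transitive ancestors (toward the root)."""
        if term not in self.parents[namespace]:
            raise UnknownTermError(term, namespace)
        seen = {term}
        stack = [term]
        while stack:
            for p in self.parents[namespace].get(stack.pop(), ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return frozenset(seen)

    def depth1_terms(self, namespace: str) -> FrozenSet[str]:
        """Terms exactly one parent-link below the namespace root."""
        root = self.roots[namespace]
        return frozenset(
            t for t, ps in self.parents[namespace].items() if root in ps
        )

    def validate(self) -> None:
        """Check acyclicity and root reachability for both namespaces."""
        for ns in _NAMESPACES:
            parents = self.parents[ns]
            if not parents:
                continue
            if ns not in self.roots:
                raise ValueError(f"{ns} namespace has no declared root")
            # cycle check via iterative DFS colouring
            WHITE, GREY, BLACK = 0, 1, 2
            colour = {t: WHITE for t in parents}
            for start in parents:
                if colour[start] != WHITE:
                    continue
                stack = [(start, iter(parents[start]))]
                colour[start] = GREY
                while stack:
                    node, it = stack[-1]
                    advanced = False
                    for p in it:
                        if colour[p] == GREY:
                            raise ValueError(f"cycle in {ns} hierarchy at {p!r}")
                        if colour[p] == WHITE:
                            colour[p] = GREY
                            stack.append((p, iter(parents[p])))
                            advanced = True
                            break
                    if not advanced:
                        colour[node] = BLACK
                        stack.pop()
            root = self.roots[ns]
            for t in parents:
                if root not in self.ancestors(ns, t):
                    raise ValueError(
                        f"{ns} term {t!r} does not reach the root {root!r}"
                    )


def term_descendants(hierarchy: OntologyHierarchy, term: str) -> FrozenSet[str]:
    """Return ``term`` plus all of its transitive children.

    The namespace is inferred from the term; raises
    :class:`UnknownTermError` if the term is in neither namespace.
    """
    ns = hierarchy.namespace_of(term)
    return hierarchy.descendants(ns, term)


def term_matches(
    hierarchy: OntologyHierarchy, candidate: str, allowed: Iterable[str]
) -> bool:
    """True iff ``allowed`` is empty or ``candidate`` descends from a member.

    An empty ``allowed`` set means the constraint is absent (unconstrained),
    which everything satisfies.  Multi-valued constraints are disjunctive.
    """
    allowed = list(allowed)
    if not allowed:
        return True
    ns = hierarchy.namespace_of(candidate)
    return any(
        candidate in hierarchy.descendants(ns, a)
        for a in allowed
        if hierarchy.has_term(ns, a)
    )
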