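"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the Fisher oracle
enumerates margin-preserving tables with exact integer arithmetic, and the
subgraph-matching oracle filters the full cartesian product of binding maps
through the declarative checker.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb
from typing import Dict, List

from kgreason import binding_fulfills


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by enumeration over all tables sharing the
    observed margins.

    The point probability of the table with top-left cell x is
    C(col1, x) * C(n - col1, row1 - x) / C(n, row1); all tables share the
    denominator, so the two-sided tail is accumulated on integer numerators
    (with the conventional 1e-7 relative tie tolerance) and converted to an
    exact rational at the end.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def numerator(x: int) -> int:
        return comb(col1, x) * comb(n - col1, row1 - x)

    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    obs = numerator(a)
    scale = 10**7
    total = sum(
        num
        for x in range(lo, hi + 1)
        if (num := numerator(x)) * scale <= obs * (scale + 1)
    )
    return float(min(Fraction(total, comb(n, row1)), Fraction(1)))


def enumerate_bindings_oracle(
    qg, kg, hierarchy, ignore_edge_direction: bool
) -> List[Dict[str, str]]:
    """All fulfilling node-binding maps by exhaustive cartesian enumeration."""
    keys = sorted(qg.nodes)
    out = []
    for combo in itertools.product(sorted(kg.nodes), repeat=len(keys)):
        binding = dict(zip(keys, combo))
        if binding_fulfills(qg, kg, binding, hierarchy, ignore_edge_direction):
            out.append(binding)
    return out
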