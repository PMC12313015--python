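"""Classic set cover baselines: greedy approximation and branch-and-bound.

Both operate on a :class:`GenericSetSystem` with uniform set cost 1 — the
formulation the vicinity problem reduces to once each vicinity becomes a set
of gene indices.  They serve as comparators and as correctness oracles for
the dynamic-programming solver: greedy is fast but only ln(n)-approximate;
branch-and-bound is exact but exponential, so it is guarded by a node limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = ["GenericSetSystem", "greedy_cover", "branch_and_bound_cover", "BnBResult"]


@dataclass
class GenericSetSystem:
    """Uniform-cost set system: 1-based set indices over universe ``1..n``."""

    universe_size: int
    sets: dict[int, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(range(1, self.universe_size + 1))
        for idx, members in self.sets.items():
            if not members:
                raise ValueError(f"set {idx} is empty")
            if not set(members) <= universe:
                raise ValueError(f"set {idx} has members outside 1..{self.universe_size}")
        covered = set().union(*self.sets.values()) if self.sets else set()
        missing = universe - covered
        if missing:
            raise ValueError(f"universe element {min(missing)} is in no set")

    @classmethod
    def from_intervals(cls, sets: Sequence, universe_size: Optional[int] = None) -> "GenericSetSystem":
        """Build from interval sets (``VicinitySet``/``IntervalSet``/tuples)."""
        members: dict[int, frozenset[int]] = {}
        hi = 0
        for k, s in enumerate(sets, start=1):
            first = getattr(s, "first", None)
            last = getattr(s, "last", None)
            if first is None or last is None:
                first, last = s[0], s[1]
            members[k] = frozenset(range(first, last + 1))
            hi = max(hi, last)
        n = universe_size if universe_size is not None else hi
        return cls(universe_size=n, sets=members)


def greedy_cover(system: GenericSetSystem) -> list[int]:
    """Greedy set cover: repeatedly take the set covering the most uncovered
    elements (ties to the smallest index).  Guarantees at most
    ``optimum * (ln n + 1)`` sets."""
    uncovered = set(range(1, system.universe_size + 1))
    chosen: list[int] = []
    while uncovered:
        best_idx, best_gain = None, 0
        for idx in sorted(system.sets):
            gain = len(system.sets[idx] & uncovered)
            if gain > best_gain:
                best_idx, best_gain = idx, gain
        if best_idx is None:
            raise ValueError(f"element {min(uncovered)} cannot be covered")
        chosen.append(best_idx)
        uncovered -= system.sets[best_idx]
    return chosen


@dataclass
class BnBResult:
    reference_indices: list[int]
    proven_optimal: bool
    nodes_explored: int

    @property
    def size(self) -> int:
        return len(self.reference_indices)


def branch_and_bound_cover(system: GenericSetSystem, node_limit: int = 10**6) -> BnBResult:
    """Exact uniform-cost set cover by depth-first branch-and-bound.

    Branches on include/exclude of the smallest-index set containing the
    lowest uncovered element; the bound adds ``ceil(uncovered / largest
    available set)`` to the current size.  The greedy solution seeds the
    incumbent.  When ``node_limit`` is exhausted the incumbent is returned
    with ``proven_optimal=False``.
    """
    universe = frozenset(range(1, system.universe_size + 1))
    incumbent = greedy_cover(system)
    best_size = len(incumbent)
    nodes = 0
    complete = True

    def lower_bound(uncovered: frozenset[int], available: frozenset[int]) -> float:
        if not uncovered:
            return 0.0
        largest = max((len(system.sets[i] & uncovered) for i in available), default=0)
        if largest == 0:
            return math.inf
        return math.ceil(len(uncovered) / largest)

    def dfs(uncovered: frozenset[int], available: frozenset[int], chosen: list[int]) -> None:
        nonlocal incumbent, best_size, nodes, complete
        if nodes >= node_limit:
            complete = False
            return
        nodes += 1
        if not uncovered:
            if len(chosen) < best_size:
                best_size = len(chosen)
                incumbent = list(chosen)
            return
        if len(chosen) + lower_bound(uncovered, available) >= best_size:
            return
        e = min(uncovered)
        candidates = [i for i in sorted(available) if e in system.sets[i]]
        if not candidates:
            return
        pick = candidates[0]
        # include branch
        chosen.append(pick)
        dfs(uncovered - system.sets[pick], available - {pick}, chosen)
        chosen.pop()
        # exclude branch (e must then come from another candidate)
        if len(candidates) > 1:
            dfs(uncovered, available - {pick}, chosen)

    dfs(universe, frozenset(system.sets), [])
    return BnBResult(
        reference_indices=sorted(incumbent),
        proven_optimal=complete,
        nodes_explored=nodes,
    )
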