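"""Dynamic-programming solver for the vicinity set cover problem.

The input is an ordered list of interval sets ``g_1..g_N`` over the universe
``1..n`` (for vicinity sets built from an annotation, N = n and set ``g_i``
contains its own reference index ``i``).  A *path* is an index-increasing
chain of sets that starts at a set reaching index 1, never leaves a gap
(each successor must start at or before the previous set's end + 1), and ends
at a set reaching index n.  The solver computes, per set, the minimum chain
length ``R_i`` reaching it:

    R_i = 1                                     if a_i = 1
    R_i = 1 + min{ R_j : j < i, b_j >= a_i - 1 }  otherwise

keeping a single best predecessor per state instead of the full list of
optimal paths; the multiplicity those lists would carry survives in
``tied_pred_count`` and in the pruned path counter.  Among predecessors tied
on ``R``, the one minimizing the accumulated per-set average estimation
distance wins; remaining ties go to the smallest index, making the solution
bit-reproducible.

Worst-case work is O(N^2) (every set can precede every other at very large
thresholds); a window pointer skips permanently invalid predecessors when the
sets' start indices are non-decreasing, which holds for all geometric inputs,
so typical runtime is near-linear.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, NamedTuple, Optional, Sequence, Union

import numpy as np

from .annotation import GeneIndex

__all__ = [
    "IntervalSet",
    "PathState",
    "CoverSolution",
    "CoverageGapError",
    "solve",
    "count_paths",
    "enumerate_min_covers",
    "assign_references",
    "is_gapless_chain",
    "PATH_COUNT_EXCEEDED",
]

TerminalMode = Literal["last_set", "optimal"]
ScoreMode = Literal["per_set", "per_member"]

#: Sentinel returned by :func:`count_paths` when the count exceeds the cap.
PATH_COUNT_EXCEEDED = math.inf


class IntervalSet(NamedTuple):
    """Lightweight interval set for hand-made instances: indices first..last."""

    first: int
    last: int
    avg_distance: float = 0.0


class CoverageGapError(ValueError):
    """The set family cannot cover the universe without a gap."""


@dataclass
class PathState:
    """Per-set DP state: minimum chain length and the retained best path."""

    set_index: int
    R: int
    dsum: float
    best_pred: Optional[int]
    tied_pred_count: int
    n_optimal_paths: int  # pruned path count (product-of-ties accounting)


@dataclass
class CoverSolution:
    """A minimum vicinity set cover with its tie-break score and diagnostics."""

    threshold: Optional[int]
    reference_indices: list[int]
    R: int
    path_score: float
    terminal_mode: TerminalMode
    score_mode: ScoreMode
    universe_size: int
    assignment: Optional[dict[int, int]] = None
    states: list[PathState] = field(default_factory=list, repr=False)
    n_optimal_paths: int = 1
    intervals: dict[int, tuple[int, int]] = field(default_factory=dict, repr=False)

    @property
    def tie_counts(self) -> list[int]:
        return [s.tied_pred_count for s in self.states]

    def summary(self) -> dict:
        return {
            "n": self.universe_size,
            "t": self.threshold,
            "R": self.R,
            "path_score": self.path_score,
            "terminal_mode": self.terminal_mode,
            "score_mode": self.score_mode,
            "reference_indices": self.reference_indices,
            "n_optimal_paths": self.n_optimal_paths,
            "max_tied_predecessors": max(self.tie_counts, default=0),
        }


def _normalize(sets: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract (a, b, d, m) arrays from VicinitySet / IntervalSet / tuples."""
    a = np.empty(len(sets), dtype=np.int64)
    b = np.empty(len(sets), dtype=np.int64)
    d = np.empty(len(sets), dtype=np.float64)
    m = np.empty(len(sets), dtype=np.int64)
    for k, s in enumerate(sets):
        first = getattr(s, "first", None)
        last = getattr(s, "last", None)
        if first is None or last is None:
            first, last = s[0], s[1]
        a[k], b[k] = first, last
        d[k] = getattr(s, "avg_distance", 0.0)
        m[k] = max(0, last - first)  # non-reference members
    if np.any(a > b):
        raise ValueError("interval set with first > last")
    if np.any(a < 1):
        raise ValueError("interval sets must live on the 1-based universe")
    return a, b, d, m


def _first_uncovered(a: np.ndarray, b: np.ndarray, n: int) -> Optional[int]:
    """Smallest universe index no gapless chain can reach, or None."""
    reach = 0
    order = np.argsort(a, kind="stable")
    for k in order:
        if a[k] <= reach + 1:
            reach = max(reach, int(b[k]))
        elif a[k] > reach + 1:
            break
    return reach + 1 if reach < n else None


def solve(
    sets: Sequence,
    terminal_mode: TerminalMode = "optimal",
    score_mode: ScoreMode = "per_set",
    universe_size: Optional[int] = None,
    threshold: Optional[int] = None,
) -> CoverSolution:
    """Find a minimum-cardinality gapless cover of ``1..n`` by ordered
    interval sets, tie-broken by smallest accumulated average distance.

    Parameters
    ----------
    sets
        Ordered interval sets (``VicinitySet``, :class:`IntervalSet`, or
        ``(first, last)`` tuples).
    terminal_mode
        ``"optimal"`` (default) minimizes over every set reaching index n;
        ``"last_set"`` forces the chain to end at the last set, which can cost
        one extra set when an earlier set already reaches n (a warning is
        issued when that happens).
    score_mode
        ``"per_set"`` accumulates each chosen set's average distance once;
        ``"per_member"`` weights it by the set's non-reference member count.
    universe_size
        Defaults to ``max(last)`` over the sets.
    """
    if not sets:
        raise ValueError("no sets")
    a, b, d, m = _normalize(sets)
    N = len(sets)
    n = int(universe_size) if universe_size is not None else int(b.max())
    weight = d * m if score_mode == "per_member" else d
    if score_mode not in ("per_set", "per_member"):
        raise ValueError(f"unknown score_mode {score_mode!r}")

    gap = _first_uncovered(a, b, n)
    if gap is not None:
        raise CoverageGapError(f"gap in coverage: gene {gap} is unreachable")

    BIG = N + 2
    R = np.full(N, BIG, dtype=np.int64)
    dsum = np.full(N, np.inf)
    msum = np.zeros(N, dtype=np.int64)
    preds: list[Optional[int]] = [None] * N
    ties = np.zeros(N, dtype=np.int64)
    npaths: list[int] = [0] * N

    a_monotone = bool(np.all(np.diff(a) >= 0))
    lo = 0
    for i in range(N):
        if a[i] == 1:
            R[i], dsum[i], msum[i] = 1, float(weight[i]), int(m[i])
            ties[i], npaths[i] = 0, 1
            continue
        x = a[i] - 1
        if a_monotone:
            while lo < i and b[lo] < x:
                lo += 1
            w0 = lo
        else:
            w0 = 0
        if w0 >= i:
            continue  # unreachable state; cover-gap already excluded above
        valid = b[w0:i] >= x
        if not valid.any():
            continue
        Rw = np.where(valid, R[w0:i], BIG)
        minR = int(Rw.min())
        if minR >= BIG:
            continue
        cand = valid & (R[w0:i] == minR)
        dw = np.where(cand, dsum[w0:i], np.inf)
        mind = dw.min()
        j = w0 + int(np.argmax(cand & (dsum[w0:i] == mind)))  # smallest tied index
        R[i] = minR + 1
        dsum[i] = mind + float(weight[i])
        msum[i] = msum[j] + int(m[i])
        preds[i] = j
        ties[i] = int(cand.sum())
        npaths[i] = sum(npaths[k] for k in (np.nonzero(cand)[0] + w0))

    ends = np.nonzero((b >= n) & (R < BIG))[0]
    if ends.size == 0:
        raise CoverageGapError(f"gap in coverage: gene {n} is unreachable")
    if terminal_mode == "last_set":
        terminal = N - 1
        if b[terminal] < n or R[terminal] >= BIG:
            raise CoverageGapError(
                "last_set terminal mode requires the last set to reach the last gene"
            )
        best_end = min(ends, key=lambda k: (R[k], dsum[k], k))
        if R[terminal] > R[best_end]:
            warnings.warn(
                f"terminal_mode='last_set' forces the chain through the last set "
                f"(R={int(R[terminal])}); an earlier terminal achieves R={int(R[best_end])}",
                stacklevel=2,
            )
    elif terminal_mode == "optimal":
        terminal = int(min(ends, key=lambda k: (R[k], dsum[k], k)))
    else:
        raise ValueError(f"unknown terminal_mode {terminal_mode!r}")

    chain: list[int] = []
    k: Optional[int] = terminal
    while k is not None:
        chain.append(k + 1)
        k = preds[k]
    chain.reverse()

    # validity: the chosen intervals tile 1..n without a gap
    reach = 0
    for idx in chain:
        if a[idx - 1] > reach + 1:
            raise AssertionError("solver produced a gapped chain")
        reach = max(reach, int(b[idx - 1]))
    if reach < n:
        raise AssertionError("solver chain does not reach the last gene")

    total = float(dsum[terminal])
    denom = len(chain) if score_mode == "per_set" else max(1, int(msum[terminal]))
    states = [
        PathState(
            set_index=i + 1,
            R=int(R[i]),
            dsum=float(dsum[i]),
            best_pred=None if preds[i] is None else preds[i] + 1,
            tied_pred_count=int(ties[i]),
            n_optimal_paths=npaths[i],
        )
        for i in range(N)
    ]
    return CoverSolution(
        threshold=threshold,
        reference_indices=chain,
        R=int(R[terminal]),
        path_score=total / denom,
        terminal_mode=terminal_mode,
        score_mode=score_mode,
        universe_size=n,
        states=states,
        n_optimal_paths=npaths[terminal],
        intervals={i + 1: (int(a[i]), int(b[i])) for i in range(N)},
    )


def count_paths(
    sets: Sequence,
    prune: bool = True,
    cap: int = 10**6,
    universe_size: Optional[int] = None,
) -> Union[int, float]:
    """Count valid gapless chains ending at the last set.

    With ``prune=True`` only chains of minimum length (optimal paths) are
    counted, mirroring the solver's criterion; with ``prune=False`` every
    valid chain counts, which grows exponentially on overlapping set
    families.  Returns :data:`PATH_COUNT_EXCEEDED` once the count passes
    ``cap``.
    """
    a, b, _, _ = _normalize(sets)
    N = len(sets)
    clamp = cap + 1
    if prune:
        sol = solve(sets, terminal_mode="last_set", universe_size=universe_size)
        count = sol.n_optimal_paths
        return count if count <= cap else PATH_COUNT_EXCEEDED
    U = [0] * N
    for i in range(N):
        c = 1 if a[i] == 1 else 0
        x = a[i] - 1
        for j in range(i):
            if b[j] >= x:
                c += U[j]
        U[i] = min(c, clamp)
    return U[N - 1] if U[N - 1] <= cap else PATH_COUNT_EXCEEDED


def is_gapless_chain(
    sets: Sequence, indices: Sequence[int], universe_size: Optional[int] = None
) -> bool:
    """True when ``indices`` (1-based, any order) form a valid solver chain:
    increasing, first set starts at 1, no coverage gap, last set reaches n."""
    a, b, _, _ = _normalize(sets)
    n = int(universe_size) if universe_size is not None else int(b.max())
    idx = sorted(int(i) - 1 for i in indices)
    if len(set(idx)) != len(idx) or not idx:
        return False
    if a[idx[0]] != 1:
        return False
    reach = 0
    for k in idx:
        if a[k] > reach + 1:
            return False
        reach = max(reach, int(b[k]))
    return reach >= n


def enumerate_min_covers(
    sets: Sequence, cap: int = 2 * 10**6, universe_size: Optional[int] = None
) -> list[list[int]]:
    """All minimum-cardinality covers of the universe, as sorted 1-based
    index lists, found by exhaustive enumeration.  Intended as a test oracle
    for small instances; raises when the enumeration budget ``cap`` (number
    of candidate subsets examined) is exceeded."""
    a, b, _, _ = _normalize(sets)
    N = len(sets)
    n = int(universe_size) if universe_size is not None else int(b.max())
    examined = 0
    for size in range(1, N + 1):
        found: list[list[int]] = []
        for combo in combinations(range(N), size):
            examined += 1
            if examined > cap:
                raise RuntimeError(
                    f"enumeration cap {cap} exceeded; use a smaller instance"
                )
            covered = np.zeros(n + 1, dtype=bool)
            for k in combo:
                covered[a[k] : b[k] + 1] = True
            if covered[1:].all():
                found.append([k + 1 for k in combo])
        if found:
            return found
    raise CoverageGapError("no cover exists")


def assign_references(solution: CoverSolution, index: GeneIndex) -> dict[int, int]:
    """Assign every gene to the nearest chosen reference whose set contains it.

    Nearness is the facing gap; ties go to the smaller reference index.
    Reference genes map to themselves.  The mapping is stored on the solution
    and returned (1-based gene index -> 1-based reference index).
    """
    refs = solution.reference_indices
    chosen = {r: solution.intervals[r] for r in refs}
    assignment: dict[int, int] = {}
    for j in range(1, solution.universe_size + 1):
        if j in chosen:
            assignment[j] = j
            continue
        best: Optional[tuple[int, int]] = None
        for r in refs:
            a_r, b_r = chosen[r]
            if a_r <= j <= b_r:
                gap = index.pair_gap(j, r)
                key = (gap, r)
                if best is None or key < best:
                    best = key
        if best is None:
            raise AssertionError(f"gene {j} not covered by any chosen set")
        assignment[j] = best[1]
    solution.assignment = assignment
    return assignment


def assignment_to_ids(assignment: dict[int, int], index: GeneIndex) -> dict[str, str]:
    """Convert an index->index assignment to gene-id -> reference-id."""
    return {index.gene(j).id: index.gene(r).id for j, r in assignment.items()}
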