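"""Dynamic-programming cover solver: optimality, tie-breaking, path counting."""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pytest

from vicinitycover import (
    CoverageGapError,
    IntervalSet,
    assign_references,
    build_sets,
    count_paths,
    enumerate_min_covers,
    is_gapless_chain,
    solve,
    worked_example_instance,
)
from conftest import random_geometric_instance


def brute_force_chain_count(sets, prune: bool) -> int:
    """Independent chain counter: DFS over index-increasing gapless chains
    ending at the last set (optionally restricted to minimum length)."""
    a = [s.first for s in sets]
    b = [s.last for s in sets]
    N = len(sets)
    chains = []

    def extend(prefix):
        i = prefix[-1]
        if a[i] == 1:
            chains.append(list(prefix))
        for j in range(i):
            if b[j] >= a[i] - 1:
                extend(prefix + [j])

    extend([N - 1])
    if not prune:
        return len(chains)
    shortest = min(len(c) for c in chains)
    return sum(1 for c in chains if len(c) == shortest)


class TestSolveExamples:
    def test_five_gene_vicinity_sets_cover_with_two_references(self):
        _, sets = worked_example_instance("five_gene_vicinity")
        sol = solve(sets, universe_size=5)
        assert sol.R == 2
        assert sorted(sol.reference_indices) in enumerate_min_covers(sets, universe_size=5)

    def test_single_set_base_case(self):
        sol = solve([IntervalSet(1, 1)])
        assert sol.R == 1 and sol.reference_indices == [1]

    def test_greedy_gap_instance_needs_only_two(self):
        _, sets = worked_example_instance("greedy_gap")
        sol = solve(sets, universe_size=8)
        assert sol.R == 2
        assert sorted(sol.reference_indices) == [1, 3]

    def test_predecessor_narrative_states(self):
        # minimum chain lengths run 1,2,2,2,2 then 3 at the sixth set, which
        # has four equally short predecessors
        _, sets = worked_example_instance("tied_predecessors")
        sol = solve(sets, terminal_mode="last_set")
        assert [s.R for s in sol.states][:6] == [1, 2, 2, 2, 2, 3]
        assert sol.states[5].tied_pred_count == 4

    def test_terminal_trap_forced_last_set_costs_one_extra(self):
        _, sets = worked_example_instance("terminal_trap")
        opt = solve(sets, terminal_mode="optimal")
        with pytest.warns(UserWarning, match="terminal_mode='last_set'"):
            forced = solve(sets, terminal_mode="last_set")
        assert opt.R == 1
        assert forced.R == opt.R + 1

    def test_gap_in_coverage_names_first_uncovered_gene(self):
        with pytest.raises(CoverageGapError, match="gene 3"):
            solve([IntervalSet(1, 2), IntervalSet(4, 5)], universe_size=5)

    def test_threshold_monotone_cover_size(self, rng):
        index, _, _ = random_geometric_instance(rng, n_min=12, n_max=20)
        sizes = []
        for t in (0, 1000, 3000, 6000, 12000, 25000):
            sets, _ = build_sets(index, t)
            sizes.append(solve(sets).R)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_chain_is_a_valid_cover(self, rng):
        for _ in range(20):
            _, _, sets = random_geometric_instance(rng)
            sol = solve(sets)
            covered = set()
            for r in sol.reference_indices:
                a, b = sol.intervals[r]
                covered |= set(range(a, b + 1))
            assert covered == set(range(1, len(sets) + 1))
            assert is_gapless_chain(sets, sol.reference_indices)

    def test_score_modes_agree_on_cover_size(self, rng):
        _, _, sets = random_geometric_instance(rng, n_min=10, n_max=16)
        per_set = solve(sets, score_mode="per_set")
        per_member = solve(sets, score_mode="per_member")
        assert per_set.R == per_member.R
        assert math.isfinite(per_member.path_score)

    def test_deterministic_reruns(self, rng):
        _, _, sets = random_geometric_instance(rng, n_min=10, n_max=18)
        a = solve(sets)
        b = solve(sets)
        assert a.reference_indices == b.reference_indices
        assert a.path_score == b.path_score


class TestCountPaths:
    def test_matches_brute_force_on_five_gene_vicinity(self):
        _, sets = worked_example_instance("five_gene_vicinity")
        assert count_paths(sets, prune=False, universe_size=5) == \
            brute_force_chain_count(sets, prune=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert count_paths(sets, prune=True, universe_size=5) == \
                brute_force_chain_count(sets, prune=True)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(10):
            _, _, sets = random_geometric_instance(rng, n_min=4, n_max=9)
            unpruned = count_paths(sets, prune=False, cap=10**9)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pruned = count_paths(sets, prune=True, cap=10**9)
            assert unpruned == brute_force_chain_count(sets, prune=False)
            assert pruned == brute_force_chain_count(sets, prune=True)
            assert pruned <= unpruned

    def test_disjoint_singleton_chain_has_one_path(self):
        sets = [IntervalSet(i, i) for i in range(1, 7)]
        assert count_paths(sets, prune=False) == 1
        assert count_paths(sets, prune=True) == 1

    def test_cap_returns_sentinel(self):
        sets = [IntervalSet(max(1, i - 3), min(30, i + 3)) for i in range(1, 31)]
        assert count_paths(sets, prune=False, cap=10) == math.inf


class TestEnumerateMinCovers:
    def test_identical_neighbor_sets_give_two_covers(self):
        _, sets = worked_example_instance("identical_neighbors")
        assert enumerate_min_covers(sets, universe_size=3) == [[1, 3], [2, 3]]

    def test_single_covering_set(self):
        sets = [IntervalSet(1, 4), IntervalSet(2, 3)]
        assert enumerate_min_covers(sets, universe_size=4) == [[1]]

    def test_disjoint_singletons_force_all_sets(self):
        sets = [IntervalSet(i, i) for i in range(1, 6)]
        assert enumerate_min_covers(sets, universe_size=5) == [[1, 2, 3, 4, 5]]

    def test_cap_raises(self):
        sets = [IntervalSet(i, i) for i in range(1, 25)]
        with pytest.raises(RuntimeError, match="cap"):
            enumerate_min_covers(sets, cap=100)


class TestAssignment:
    def test_forced_and_tied_assignments(self):
        from conftest import make_uniform

        index = make_uniform(3)  # pitch 2500, gaps 1000 either side of gene 2
        sets, _ = build_sets(index, 1000)
        sol = solve(sets)
        assignment = assign_references(sol, index)
        assert sol.R == 1 and sol.reference_indices == [2]
        assert assignment == {1: 2, 2: 2, 3: 2}

    def test_equidistant_tie_goes_to_smaller_reference(self):
        from conftest import make_uniform

        index = make_uniform(7)
        sets, _ = build_sets(index, 1000)  # every set spans ref +/- 1
        sol = solve(sets)
        assignment = assign_references(sol, index)
        refs = sol.reference_indices
        saw_tie = False
        for j, r in assignment.items():
            ties = [
                r2 for r2 in refs
                if sol.intervals[r2][0] <= j <= sol.intervals[r2][1]
                and index.pair_gap(j, r2) == index.pair_gap(j, r)
            ]
            saw_tie = saw_tie or len(ties) > 1
            assert r == min(ties)
        assert saw_tie

    def test_assignment_distance_never_exceeds_threshold(self, rng):
        for _ in range(15):
            index, t, sets = random_geometric_instance(rng)
            if any(s.closure_added for s in sets):
                continue  # closure members may legitimately sit beyond t
            sol = solve(sets, threshold=t)
            assignment = assign_references(sol, index)
            for j, r in assignment.items():
                assert index.pair_gap(j, r) <= t
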