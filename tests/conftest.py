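"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import pytest

from coregnet import RegulatoryNetwork


@pytest.fixture
def toy_net() -> RegulatoryNetwork:
    """A -> {g1,g2}, B -> {g2,g3}, C -> {g4}: one co-targeting pair."""
    return RegulatoryNetwork(
        [("A", "g1"), ("A", "g2"), ("B", "g2"), ("B", "g3"), ("C", "g4")],
        name="toy")


@pytest.fixture
def complete_bipartite() -> RegulatoryNetwork:
    """2 regulators x 3 targets, all edges present (margins force it)."""
    return RegulatoryNetwork(
        [(r, t) for r in ("R1", "R2") for t in ("t1", "t2", "t3")],
        name="k23")


def fixed_margin_bipartite_graphs(row_sums: list[int], n_cols: int,
                                  col_sums: list[int]):
    """Enumerate all 0/1 bipartite graphs with the given margins.

    Yields one tuple of frozensets (column indices per row) per graph.
    Brute force over per-row column subsets; only for tiny instances.
    """

    def rec(row: int, remaining: list[int], acc: list[frozenset]):
        if row == len(row_sums):
            if all(r == 0 for r in remaining):
                yield tuple(acc)
            return
        for cols in combinations(range(n_cols), row_sums[row]):
            if any(remaining[c] == 0 for c in cols):
                continue
            for c in cols:
                remaining[c] -= 1
            acc.append(frozenset(cols))
            yield from rec(row + 1, remaining, acc)
            acc.pop()
            for c in cols:
                remaining[c] += 1

    yield from rec(0, list(col_sums), [])


def exact_mean_shared(row_sums: list[int], n_cols: int, col_sums: list[int],
                      i: int = 0, j: int = 1) -> float:
    """Exact E[|row_i ∩ row_j|] under the uniform fixed-margin ensemble."""
    total = 0
    count = 0
    for graph in fixed_margin_bipartite_graphs(row_sums, n_cols, col_sums):
        total += len(graph[i] & graph[j])
        count += 1
    assert count > 0, "no realizations for these margins"
    return total / count
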