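"""Degree-preserving randomization and null co-targeting statistics.

The null model keeps every node's in- and out-degree exactly while
making partner choice otherwise random.  Randomization is by attempted
double edge swaps: pick two edges (r1, t1), (r2, t2) and rewire to
(r1, t2), (r2, t1), rejecting any swap that would duplicate an existing
edge (or create a self-edge the input did not license).  This proposal
is symmetric and connects the space of bipartite-role graphs with fixed
margins, so with enough attempts the sampled networks are uniform over
that space.

``null_cotarget_stats`` builds an ensemble of such networks (the
study-grade default is 1,000) and records, per regulator pair, the mean
and SD of the shared-target count — the (mu, sigma) behind the CC and
z-score edge filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .network import RegulatoryNetwork

__all__ = [
    "NullEnsembleStats",
    "shuffle_preserving_degrees",
    "null_cotarget_stats",
]

Pair = tuple[str, str]

DEFAULT_SWAP_FACTOR = 10.0
DEFAULT_ENSEMBLE_SIZE = 1000


@dataclass
class NullEnsembleStats:
    """Per-pair null mean/SD of shared-target counts.

    Keys cover every unordered regulator pair with a positive shared
    count in the real network or in at least one ensemble replicate;
    SDs use the population convention (ddof = 0).
    """

    pair_mean: dict[Pair, float]
    pair_sd: dict[Pair, float]
    ensemble_size: int
    seed: int
    swap_factor: float = DEFAULT_SWAP_FACTOR

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("regulator_1\tregulator_2\tmu\tsigma\tensemble_size\n")
            for (r1, r2) in sorted(self.pair_mean):
                fh.write(f"{r1}\t{r2}\t{self.pair_mean[(r1, r2)]:.6g}\t"
                         f"{self.pair_sd[(r1, r2)]:.6g}\t{self.ensemble_size}\n")


# ---------------------------------------------------------------------------
# integer-encoded edge store for the hot swap loop


def _encode(net: RegulatoryNetwork):
    """Map node ids to ints and edges to parallel (reg, tgt) index lists."""
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = sorted(net.edges)
    regs = [index[r] for r, _ in edges]
    tgts = [index[t] for _, t in edges]
    return nodes, regs, tgts


def _attempt_swaps(regs: list[int], tgts: list[int], n_nodes: int,
                   attempts: int, rng: np.random.Generator,
                   allow_self: bool) -> int:
    """In-place double edge swaps; returns the number accepted.

    Edges are encoded as reg * n_nodes + tgt in a hash set for O(1)
    duplicate checks; the loop is plain Python over pre-drawn random
    index pairs, which keeps per-attempt cost low without a compiled
    extension.
    """
    n = len(regs)
    if n < 2 or attempts <= 0:
        return 0
    codes = {r * n_nodes + t for r, t in zip(regs, tgts)}
    ii = rng.integers(0, n, size=attempts).tolist()
    jj = rng.integers(0, n, size=attempts).tolist()
    accepted = 0
    for i, j in zip(ii, jj):
        r1 = regs[i]
        t1 = tgts[i]
        r2 = regs[j]
        t2 = tgts[j]
        if r1 == r2 or t1 == t2:
            continue
        c1 = r1 * n_nodes + t2
        c2 = r2 * n_nodes + t1
        if c1 in codes or c2 in codes:
            continue
        if not allow_self and (r1 == t2 or r2 == t1):
            continue
        codes.remove(r1 * n_nodes + t1)
        codes.remove(r2 * n_nodes + t2)
        codes.add(c1)
        codes.add(c2)
        tgts[i] = t2
        tgts[j] = t1
        accepted += 1
    return accepted


def shuffle_preserving_degrees(net: RegulatoryNetwork,
                               swap_factor: float = DEFAULT_SWAP_FACTOR,
                               seed: int | np.random.Generator | None = 0
                               ) -> RegulatoryNetwork:
    """Return a degree-preserving randomization of ``net``.

    Performs ``ceil(swap_factor * |edges|)`` attempted double edge
    swaps.  Every regulator keeps its out-degree and every target its
    in-degree; no duplicate edges are introduced, and self-edges can
    only arise if the input already contained some.  Networks whose
    margins force a unique edge set come back unchanged.
    """
    if len(net.edges) < 2:
        return RegulatoryNetwork(net.edges, nodes=net.nodes, name=net.name)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    nodes, regs, tgts = _encode(net)
    attempts = int(np.ceil(swap_factor * len(regs)))
    _attempt_swaps(regs, tgts, len(nodes), attempts, rng,
                   allow_self=net.has_self_edges())
    edges = {(nodes[r], nodes[t]) for r, t in zip(regs, tgts)}
    return RegulatoryNetwork(edges, nodes=net.nodes, name=net.name)


def _pair_counts_int(regs: list[int], tgts: list[int]) -> dict[tuple[int, int], int]:
    """Shared-target counts over int-encoded edges (sorted int pairs)."""
    by_target: dict[int, list[int]] = {}
    for r, t in zip(regs, tgts):
        by_target.setdefault(t, []).append(r)
    counts: dict[tuple[int, int], int] = {}
    for rs in by_target.values():
        if len(rs) < 2:
            continue
        rs.sort()
        for a in range(len(rs) - 1):
            ra = rs[a]
            for b in range(a + 1, len(rs)):
                key = (ra, rs[b])
                counts[key] = counts.get(key, 0) + 1
    return counts


def null_cotarget_stats(net: RegulatoryNetwork,
                        ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
                        swap_factor: float = DEFAULT_SWAP_FACTOR,
                        seed: int = 0) -> NullEnsembleStats:
    """Ensemble mean/SD of shared-target counts per regulator pair.

    Each replicate is an independent randomization of the real network
    (its own swap chain, seeded from the master seed), so statistics
    are reproducible for fixed (seed, ensemble_size, swap_factor).
    Pairs that never share a target in the real network or any
    replicate are omitted (their partnership edge never exists).
    """
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    nodes, regs0, tgts0 = _encode(net)
    n_nodes = len(nodes)
    attempts = int(np.ceil(swap_factor * len(regs0)))
    allow_self = net.has_self_edges()

    sums: dict[tuple[int, int], float] = {}
    sumsq: dict[tuple[int, int], float] = {}
    # real pairs seed the key set so x>0, mu=0 pairs are representable
    for key in _pair_counts_int(regs0, tgts0):
        sums[key] = 0.0
        sumsq[key] = 0.0

    child_seeds = np.random.SeedSequence(seed).spawn(ensemble_size)
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        regs = regs0.copy()
        tgts = tgts0.copy()
        _attempt_swaps(regs, tgts, n_nodes, attempts, rng, allow_self)
        for key, c in _pair_counts_int(regs, tgts).items():
            sums[key] = sums.get(key, 0.0) + c
            sumsq[key] = sumsq.get(key, 0.0) + c * c

    r = float(ensemble_size)
    pair_mean: dict[Pair, float] = {}
    pair_sd: dict[Pair, float] = {}
    for (a, b), s in sums.items():
        mu = s / r
        var = max(sumsq[(a, b)] / r - mu * mu, 0.0)
        key = (nodes[a], nodes[b])
        key = key if key[0] <= key[1] else (key[1], key[0])
        pair_mean[key] = mu
        pair_sd[key] = float(np.sqrt(var))
    return NullEnsembleStats(pair_mean, pair_sd, ensemble_size, seed, swap_factor)
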