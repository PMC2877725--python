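"""Explanatory models for partnership saturation.

Two models account for the exponential-saturation relationship between
a regulator's number of targets (k) and its number of co-regulatory
partners (f):

1. Random target acquisition (closed form).  With m potential partner
   regulators, N available targets and n targets per regulator on
   average, a regulator acquiring targets uniformly at random gains
   partners at rate df/dk = (n/N)(m - f): each new target is regulated
   by a given not-yet-partner with probability ~ n/N.  Solving with
   f(0) = 0 gives

       f(k) = m (1 - e^(-(n/N) k)),

   the saturation curve with plateau a = m and rate b = n/N.  The
   Monte-Carlo counterpart (``simulate_random_acquisition``) is the
   brute-force oracle for this formula; it is exact only while the
   target pool is dilute (n m << N).

2. A generative network-growth simulator (``simulate_growth``).
   Starting from one TF regulating one TG, the network evolves by a
   probabilistic move set: node addition, duplication with partial edge
   inheritance, TF-to-TG conversion, and edge/node turnover.  Networks
   grown this way, run through the partnership pipeline, reproduce the
   saturation behaviour without any explicit target-pool assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .fits import PartnerTargetSeries
from .network import RegulatoryNetwork

__all__ = [
    "AcquisitionParams",
    "analytic_partner_curve",
    "simulate_random_acquisition",
    "GrowthConfig",
    "GrowthResult",
    "simulate_growth",
    "MOVES",
]


# ---------------------------------------------------------------------------
# random-acquisition model


@dataclass(frozen=True)
class AcquisitionParams:
    """Parameters of the random-acquisition model.

    m : potential partner regulators; the curve's plateau.
    N : size of the available target pool.
    n : mean targets per regulator; b = n/N is the approach rate.

    The closed form assumes a dilute pool (n*m << N); ``pool_dilution``
    = n*m/N quantifies how far a parameter set is from that regime.
    """

    m: int
    N: int
    n: float

    def __post_init__(self):
        if self.m < 1 or self.N < 1:
            raise ValueError("m and N must be >= 1")
        if not 0 < self.n <= self.N:
            raise ValueError("n must satisfy 0 < n <= N")

    @property
    def pool_dilution(self) -> float:
        return self.n * self.m / self.N


def analytic_partner_curve(params: AcquisitionParams, k) -> np.ndarray | float:
    """Expected partners f(k) = m(1 - e^(-(n/N) k)); vectorized in k."""
    k_arr = np.asarray(k, dtype=float)
    f = params.m * (1.0 - np.exp(-(params.n / params.N) * k_arr))
    return float(f) if np.isscalar(k) else f


def simulate_random_acquisition(params: AcquisitionParams, k_max: int,
                                replicates: int = 500, seed: int = 0
                                ) -> PartnerTargetSeries:
    """Monte-Carlo oracle for the random-acquisition closed form.

    A focal regulator joins a background of ``params.m`` regulators
    whose regulon sizes are Poisson(n) draws of distinct uniform
    targets ("on average, each regulator has n targets").  The focal
    regulator acquires k = 1..k_max distinct targets uniformly at
    random; f(k) is the number of background regulators sharing at
    least one target after the k-th acquisition, averaged over
    independent replicates (background regulons redrawn each time, so
    standard errors are valid).

    With Poisson regulon sizes the per-partner overlap probability is
    exactly 1 - e^(-n k / N) up to a O(n k^2/N^2) without-replacement
    correction, so in the dilute regime the simulated mean tracks the
    closed form and deviates systematically only as n*m approaches N.
    """
    if k_max > params.N:
        raise ValueError(f"k_max ({k_max}) cannot exceed N ({params.N})")
    if k_max < 1 or replicates < 1:
        raise ValueError("k_max and replicates must be >= 1")
    m, n_pool, n_mean = params.m, params.N, params.n
    f_by_rep = np.empty((replicates, k_max), dtype=float)
    for rep, ss in enumerate(np.random.SeedSequence(seed).spawn(replicates)):
        rng = np.random.default_rng(ss)
        focal = rng.choice(n_pool, size=k_max, replace=False)
        # position of each pool target in the focal acquisition order
        order = np.full(n_pool, k_max, dtype=np.int64)
        order[focal] = np.arange(k_max)
        sizes = np.minimum(rng.poisson(n_mean, size=m), n_pool)
        # first-overlap time per background regulator
        first = np.full(m, k_max, dtype=np.int64)
        for j in range(m):
            if sizes[j] > 0:
                first[j] = order[rng.choice(n_pool, size=sizes[j],
                                            replace=False)].min()
        # f(k) = number of background regulators with first overlap < k
        hist = np.bincount(first[first < k_max], minlength=k_max)
        f_by_rep[rep] = np.cumsum(hist)
    mean_f = f_by_rep.mean(axis=0)
    se_f = f_by_rep.std(axis=0, ddof=1) / math.sqrt(replicates)
    ks = np.arange(1, k_max + 1, dtype=float)
    ids = tuple(f"k{int(k)}" for k in ks)
    return PartnerTargetSeries(ids, ks, mean_f, f_se=se_f)


# ---------------------------------------------------------------------------
# generative growth model


MOVES = ("add_tf", "add_tg", "dup_tf", "dup_tg", "tf_to_tg",
         "add_edge", "del_edge", "del_node")

#: Move probabilities chosen so a 10,000-iteration run lands near the
#: output scale of curated bacterial-to-yeast transcriptional networks
#: (~1.6e2 TFs regulating ~2e3 TGs with a mean regulon of a few tens of
#: genes): node-birth rates set the TF and TG tallies directly, and
#: edge turnover dominates the move budget so regulons are dense enough
#: for co-regulation to be observable.  Configurable, not calibrated to
#: any single species.
DEFAULT_MOVE_PROBS: dict[str, float] = {
    "add_tg": 0.126, "add_tf": 0.009, "dup_tg": 0.100, "dup_tf": 0.009,
    "tf_to_tg": 0.002, "add_edge": 0.674, "del_edge": 0.060,
    "del_node": 0.020,
}

_ADD_EDGE_MAX_TRIES = 50


@dataclass(frozen=True)
class GrowthConfig:
    """Configuration of the generative growth simulator.

    ``move_probs`` must sum to 1 (tolerance 1e-9) over the recognised
    move set; ``inheritance_rate`` is the per-edge copy probability at
    duplication (default 0.30 for both TFs and TGs); ``iterations`` is
    an exact move budget (moves with no legal action are skipped and
    counted, not resampled).
    """

    move_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOVE_PROBS))
    inheritance_rate: float = 0.30
    iterations: int = 10_000
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.move_probs) - set(MOVES)
        if unknown:
            raise ValueError(f"unknown move(s): {sorted(unknown)}")
        if any(p < 0 for p in self.move_probs.values()):
            raise ValueError("move probabilities must be nonnegative")
        total = sum(self.move_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"move probabilities must sum to 1, got {total}")
        if not 0.0 <= self.inheritance_rate <= 1.0:
            raise ValueError("inheritance_rate must be in [0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


class _IndexedSet:
    """Set with O(1) uniform random choice (swap-pop removal)."""

    def __init__(self):
        self._items: list = []
        self._pos: dict = {}

    def add(self, x) -> None:
        if x not in self._pos:
            self._pos[x] = len(self._items)
            self._items.append(x)

    def remove(self, x) -> None:
        pos = self._pos.pop(x)
        last = self._items.pop()
        if pos < len(self._items):
            self._items[pos] = last
            self._pos[last] = pos

    def choice(self, rng: np.random.Generator):
        return self._items[int(rng.integers(0, len(self._items)))]

    def __contains__(self, x) -> bool:
        return x in self._pos

    def __len__(self) -> int:
        return len(self._items)


@dataclass
class GrowthResult:
    """Final grown network plus per-move audit counts.

    ``num_tfs``/``num_tgs`` count nodes by role label (a converted
    TF-TG node counts in both); audit applied+skipped counts sum to the
    configured iteration budget.
    """

    network: RegulatoryNetwork
    audit: dict[str, dict[str, int]]
    num_tfs: int
    num_tgs: int
    edge_trace: list[int] | None = None  # per-iteration edge counts

    @property
    def total_moves(self) -> int:
        return sum(c["applied"] + c["skipped"] for c in self.audit.values())


def simulate_growth(config: GrowthConfig, trace: bool = False) -> GrowthResult:
    """Grow a regulatory network from one TF regulating one TG.

    Each iteration draws one move from ``config.move_probs``:

    - add_tf / add_tg: a new, edgeless node of that role.
    - dup_tf / dup_tg: copy a uniformly chosen node of that role; each
      incident edge of the selected role (out-edges for TFs, in-edges
      for TGs) is inherited independently with ``inheritance_rate``.
    - tf_to_tg: a uniformly chosen TF becomes regulated by another
      uniformly chosen TF while keeping all its outgoing interactions
      (it now holds both roles and stays eligible for TF moves).
    - add_edge: a uniform (TF, TG) non-edge (rejection-sampled;
      skipped if none found), self-edges excluded.
    - del_edge: a uniform existing edge.
    - del_node: a uniform node with its incident edges.

    Moves with no legal action are skipped and counted.  Bit-for-bit
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    moves = list(MOVES)
    probs = np.array([config.move_probs.get(mv, 0.0) for mv in moves])
    draw = rng.choice(len(moves), size=config.iterations, p=probs)

    tfs = _IndexedSet()
    tgs = _IndexedSet()
    all_nodes = _IndexedSet()
    edges = _IndexedSet()
    out_adj: dict[int, set[int]] = {}
    in_adj: dict[int, set[int]] = {}
    next_id = 0
    rate = config.inheritance_rate

    def new_node(role: str) -> int:
        nonlocal next_id
        node = next_id
        next_id += 1
        all_nodes.add(node)
        (tfs if role == "tf" else tgs).add(node)
        out_adj[node] = set()
        in_adj[node] = set()
        return node

    def add_edge(u: int, v: int) -> None:
        edges.add((u, v))
        out_adj[u].add(v)
        in_adj[v].add(u)

    def del_edge(u: int, v: int) -> None:
        edges.remove((u, v))
        out_adj[u].discard(v)
        in_adj[v].discard(u)

    tf0 = new_node("tf")
    tg0 = new_node("tg")
    add_edge(tf0, tg0)

    audit = {mv: {"applied": 0, "skipped": 0} for mv in moves}
    edge_trace: list[int] | None = [] if trace else None

    for mv_idx in draw:
        mv = moves[mv_idx]
        applied = True
        if mv == "add_tf":
            new_node("tf")
        elif mv == "add_tg":
            new_node("tg")
        elif mv == "dup_tf":
            if len(tfs) == 0:
                applied = False
            else:
                src = tfs.choice(rng)
                dup = new_node("tf")
                for t in sorted(out_adj[src]):
                    if rng.random() < rate:
                        add_edge(dup, t)
        elif mv == "dup_tg":
            if len(tgs) == 0:
                applied = False
            else:
                src = tgs.choice(rng)
                dup = new_node("tg")
                for r in sorted(in_adj[src]):
                    if rng.random() < rate:
                        add_edge(r, dup)
        elif mv == "tf_to_tg":
            if len(tfs) < 2:
                applied = False
            else:
                node = tfs.choice(rng)
                reg = tfs.choice(rng)
                while reg == node:
                    reg = tfs.choice(rng)
                if (reg, node) in edges:
                    applied = False
                else:
                    add_edge(reg, node)
                    tgs.add(node)
        elif mv == "add_edge":
            if len(tfs) == 0 or len(tgs) == 0:
                applied = False
            else:
                applied = False
                for _ in range(_ADD_EDGE_MAX_TRIES):
                    u = tfs.choice(rng)
                    v = tgs.choice(rng)
                    if u != v and (u, v) not in edges:
                        add_edge(u, v)
                        applied = True
                        break
        elif mv == "del_edge":
            if len(edges) == 0:
                applied = False
            else:
                del_edge(*edges.choice(rng))
        elif mv == "del_node":
            if len(all_nodes) == 0:
                applied = False
            else:
                node = all_nodes.choice(rng)
                for t in sorted(out_adj[node]):
                    del_edge(node, t)
                for r in sorted(in_adj[node]):
                    del_edge(r, node)
                all_nodes.remove(node)
                if node in tfs:
                    tfs.remove(node)
                if node in tgs:
                    tgs.remove(node)
                del out_adj[node]
                del in_adj[node]
        audit[mv]["applied" if applied else "skipped"] += 1
        if edge_trace is not None:
            edge_trace.append(len(edges))

    width = max(len(str(next_id)), 1)
    name_of = {v: f"n{v:0{width}d}" for v in all_nodes._items}
    net = RegulatoryNetwork(
        ((name_of[u], name_of[v]) for u, v in edges._items),
        nodes=name_of.values(), name="grown")
    return GrowthResult(net, audit, num_tfs=len(tfs), num_tgs=len(tgs),
                        edge_trace=edge_trace)
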