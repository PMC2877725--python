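"""Co-regulation (partnership) networks.

Two regulators are partners when they control at least one common
target.  Each candidate partnership is scored against a
degree-preserving randomized ensemble: for a pair with real shared
count x and null mean/SD (mu, sigma),

    CC = x / mu            (co-regulation coefficient)
    z  = (x - mu) / sigma

and the filtered network keeps edges with CC > 1 (default), z above a
threshold, or everything (``filter='none'``).  A pair that never
co-occurs in the null ensemble but does in the real network has
CC = +inf and is always retained by the CC filter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Literal, Mapping

import networkx as nx

from .network import RegulatoryNetwork
from .nullmodel import NullEnsembleStats

__all__ = [
    "CoRegulationNetwork",
    "cotarget_counts",
    "build_coregulation",
    "partner_counts",
    "co_regulated_targets",
]

Pair = tuple[str, str]
EdgeFilter = Literal["cc", "z", "none"]

_DEFAULT_THRESHOLDS = {"cc": 1.0, "z": 0.0, "none": 0.0}


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass
class CoRegulationNetwork:
    """Undirected partnership graph over regulators.

    ``graph`` nodes are all regulators of the source network (including
    partner-less ones); edges carry the annotations x (shared-target
    count), mu, sigma, cc and z.  ``z`` is None when sigma = 0 and
    ``cc`` is +inf when mu = 0 with x > 0.
    """

    graph: nx.Graph
    filter_applied: EdgeFilter
    threshold: float
    provenance: dict = field(default_factory=dict)

    @property
    def regulators(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def num_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, dict]]:
        return self.graph.edges(data=True)

    def degree(self, regulator: str) -> int:
        return self.graph.degree(regulator)

    def to_tsv(self, path, provenance_path=None) -> None:
        """Write edges as TSV (inf/NA sentinels) plus a provenance JSON."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("regulator_1\tregulator_2\tx\tmu\tsigma\tcc\tz\n")
            for r1, r2, d in sorted(self.graph.edges(data=True)):
                cc = "inf" if math.isinf(d["cc"]) else f"{d['cc']:.6g}"
                z = "NA" if d["z"] is None else f"{d['z']:.6g}"
                fh.write(f"{r1}\t{r2}\t{d['x']}\t{d['mu']:.6g}\t"
                         f"{d['sigma']:.6g}\t{cc}\t{z}\n")
        if provenance_path is not None:
            header = {"filter": self.filter_applied, "threshold": self.threshold,
                      **self.provenance}
            with open(provenance_path, "w", encoding="utf-8") as fh:
                json.dump(header, fh, indent=2, sort_keys=True)
                fh.write("\n")


def cotarget_counts(net: RegulatoryNetwork) -> dict[Pair, int]:
    """Shared-target count for every regulator pair that shares >= 1.

    Computed by inverting the edge list (target -> regulators) so the
    cost scales with co-regulation incidences, not with all pairs.
    """
    counts: dict[Pair, int] = {}
    for regs in net.in_map.values():
        if len(regs) < 2:
            continue
        for a, b in combinations(sorted(regs), 2):
            key = (a, b)
            counts[key] = counts.get(key, 0) + 1
    return counts


def build_coregulation(net: RegulatoryNetwork, stats: NullEnsembleStats,
                       filter: EdgeFilter = "cc",
                       threshold: float | None = None) -> CoRegulationNetwork:
    """Assemble and filter the partnership network.

    Every pair with a positive real shared count must be covered by
    ``stats`` (KeyError naming the pair otherwise).  Annotations are
    computed wherever defined regardless of the filter:

    - ``filter='cc'``: keep pairs with x/mu > threshold (default 1);
      mu = 0 means CC = +inf and the pair is kept.
    - ``filter='z'``: keep pairs with (x - mu)/sigma > threshold
      (default 0); when sigma = 0 the z-score is undefined and the pair
      is kept iff x > mu.
    - ``filter='none'``: keep every co-targeting pair.
    """
    if filter not in _DEFAULT_THRESHOLDS:
        raise ValueError(f"unknown filter {filter!r}")
    if threshold is None:
        threshold = _DEFAULT_THRESHOLDS[filter]
    if filter == "cc" and threshold < 0:
        raise ValueError("cc threshold must be nonnegative")

    counts = cotarget_counts(net)
    g = nx.Graph()
    g.add_nodes_from(sorted(net.regulators))
    for pair, x in sorted(counts.items()):
        try:
            mu = stats.pair_mean[pair]
            sigma = stats.pair_sd[pair]
        except KeyError:
            raise KeyError(f"null-ensemble statistics missing for pair {pair}") \
                from None
        cc = x / mu if mu > 0 else math.inf
        z = (x - mu) / sigma if sigma > 0 else None
        if filter == "cc":
            keep = cc > threshold
        elif filter == "z":
            keep = z > threshold if z is not None else x > mu
        else:
            keep = True
        if keep:
            g.add_edge(*pair, x=x, mu=mu, sigma=sigma, cc=cc, z=z)
    provenance = {"ensemble_size": stats.ensemble_size, "seed": stats.seed,
                  "swap_factor": stats.swap_factor, "network": net.name}
    return CoRegulationNetwork(g, filter, float(threshold), provenance)


def partner_counts(coreg: CoRegulationNetwork) -> dict[str, int]:
    """Partnership degree f per regulator (0 for partner-less ones)."""
    return {r: d for r, d in coreg.graph.degree()}


def co_regulated_targets(net: RegulatoryNetwork) -> nx.Graph:
    """Target-level dual: edge between two targets sharing a regulator.

    Built unfiltered — the null-model filter applies only to the
    regulator-level partnership network.  Each regulon contributes a
    clique over its targets.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(net.targets))
    for targets in net.out_map.values():
        if len(targets) < 2:
            continue
        g.add_edges_from(combinations(sorted(targets), 2))
    return g
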