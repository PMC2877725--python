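"""Synthetic regulatory networks with the statistical shape the
analysis assumes.

Three generators cover the study designs downstream stages need:

- ``make_bipartite_network``: m regulators each draw an out-degree from
  a fixed / Poisson / power-law law and sample that many distinct
  targets uniformly from a pool of N.  The power-law law emulates the
  inhomogeneous out-connectivity of real regulatory networks.
- ``make_operon_network``: bacterial-style networks where regulators
  bind operons and every regulated operon expands to all its member
  genes; the returned gene->operon map inverts the expansion exactly.
- ``make_saturation_scatter``: noisy (x, y) points from the saturation
  curve y = a(1 - e^(-b x)), for fit-recovery experiments.

All generators are reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .fits import PartnerTargetSeries
from .network import OperonMap, RegulatoryNetwork

__all__ = [
    "SynthNetworkSpec",
    "OperonSpec",
    "make_bipartite_network",
    "make_operon_network",
    "make_saturation_scatter",
]

DegreeLaw = Literal["fixed", "poisson", "powerlaw"]


@dataclass(frozen=True)
class SynthNetworkSpec:
    """Recipe for a random bipartite regulator -> target network.

    ``mean_out_degree`` parameterizes the fixed and poisson laws;
    ``exponent`` (gamma > 0) the power law p(k) proportional to
    k^-gamma on k = 1..min(num_targets, max_out_degree).  Sampled
    out-degrees are clipped to [1, num_targets]; ``max_out_degree``
    optionally truncates the law's support below num_targets (real
    regulons are bounded well below the full gene complement).
    ``allow_shared_targets=False`` gives every regulator a disjoint
    target slice — an analytic null in which no co-regulation exists.
    """

    num_regulators: int
    num_targets: int
    out_degree_law: DegreeLaw = "powerlaw"
    mean_out_degree: float | None = None
    exponent: float | None = None
    max_out_degree: int | None = None
    allow_shared_targets: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.num_regulators < 1 or self.num_targets < 1:
            raise ValueError("num_regulators and num_targets must be >= 1")
        if self.out_degree_law in ("fixed", "poisson"):
            if self.mean_out_degree is None or self.mean_out_degree <= 0:
                raise ValueError(f"{self.out_degree_law!r} law needs a positive "
                                 "mean_out_degree")
        elif self.out_degree_law == "powerlaw":
            if self.exponent is None or self.exponent <= 0:
                raise ValueError("'powerlaw' law needs a positive exponent")
        else:
            raise ValueError(f"unknown out_degree_law {self.out_degree_law!r}")


@dataclass(frozen=True)
class OperonSpec:
    """Recipe for grouping target genes into operons.

    Operon sizes follow ``genes_per_operon_law``: 'fixed' uses
    round(mean) genes per operon; 'shifted_poisson' uses
    1 + Poisson(mean - 1); 'geometric' uses a geometric distribution on
    {1, 2, ...} with the requested mean — the skewed many-singletons /
    few-large-operons shape of real bacterial genomes.  All laws keep
    the requested mean and guarantee at least one gene per operon.
    """

    num_operons: int
    genes_per_operon_law: Literal["fixed", "shifted_poisson",
                                  "geometric"] = "geometric"
    mean_genes_per_operon: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.num_operons < 1:
            raise ValueError("num_operons must be >= 1")
        if self.mean_genes_per_operon < 1:
            raise ValueError("mean_genes_per_operon must be >= 1")


def _sample_out_degrees(spec: SynthNetworkSpec, rng: np.random.Generator
                        ) -> np.ndarray:
    m, n_targets = spec.num_regulators, spec.num_targets
    cap = n_targets if spec.max_out_degree is None \
        else min(spec.max_out_degree, n_targets)
    if spec.out_degree_law == "fixed":
        deg = np.full(m, int(round(spec.mean_out_degree)))
    elif spec.out_degree_law == "poisson":
        deg = rng.poisson(spec.mean_out_degree, size=m)
    else:  # powerlaw: discrete inverse transform on k = 1..cap
        ks = np.arange(1, cap + 1, dtype=float)
        p = ks ** -spec.exponent
        p /= p.sum()
        deg = rng.choice(np.arange(1, cap + 1), size=m, p=p)
    return np.clip(deg, 1, cap)


def _reg_names(m: int) -> list[str]:
    width = len(str(m))
    return [f"R{i + 1:0{width}d}" for i in range(m)]


def make_bipartite_network(spec: SynthNetworkSpec) -> RegulatoryNetwork:
    """Sample a random bipartite regulatory network per ``spec``."""
    rng = np.random.default_rng(spec.seed)
    degrees = _sample_out_degrees(spec, rng)
    n = spec.num_targets
    width = len(str(n))
    target_names = [f"T{j + 1:0{width}d}" for j in range(n)]
    edges: set[tuple[str, str]] = set()
    if spec.allow_shared_targets:
        for reg, d in zip(_reg_names(spec.num_regulators), degrees):
            for j in rng.choice(n, size=int(d), replace=False):
                edges.add((reg, target_names[j]))
    else:
        if int(degrees.sum()) > n:
            raise ValueError(
                f"disjoint target sets infeasible: total out-degree "
                f"{int(degrees.sum())} exceeds num_targets {n}")
        start = 0
        for reg, d in zip(_reg_names(spec.num_regulators), degrees):
            for j in range(start, start + int(d)):
                edges.add((reg, target_names[j]))
            start += int(d)
    return RegulatoryNetwork(edges, name=f"synth-{spec.out_degree_law}")


def make_operon_network(spec: SynthNetworkSpec, ops: OperonSpec
                        ) -> tuple[RegulatoryNetwork, OperonMap]:
    """Sample an operon-structured network at gene resolution.

    Regulators sample target *operons* using ``spec``'s out-degree law
    (``spec.num_targets`` must equal ``ops.num_operons`` — the operon
    pool is the sampling pool); each regulated operon then expands to
    all its member genes.  Collapsing the returned gene-level network
    with the returned map recovers the operon-level network exactly.
    """
    if spec.num_targets != ops.num_operons:
        raise ValueError("spec.num_targets must equal ops.num_operons "
                         "(regulators sample from the operon pool)")
    rng = np.random.default_rng(spec.seed)
    op_rng = np.random.default_rng(ops.seed)
    n_ops = ops.num_operons
    width = len(str(n_ops))
    operon_names = [f"OP{j + 1:0{width}d}" for j in range(n_ops)]
    if ops.genes_per_operon_law == "fixed":
        sizes = np.full(n_ops, int(round(ops.mean_genes_per_operon)))
    elif ops.genes_per_operon_law == "shifted_poisson":
        sizes = 1 + op_rng.poisson(ops.mean_genes_per_operon - 1.0, size=n_ops)
    else:  # geometric on {1, 2, ...} with the requested mean
        sizes = op_rng.geometric(1.0 / ops.mean_genes_per_operon, size=n_ops)
    genes: dict[str, list[str]] = {}
    mapping: dict[str, str] = {}
    for op, size in zip(operon_names, sizes):
        members = [f"{op}_G{g + 1}" for g in range(int(size))]
        genes[op] = members
        for gene in members:
            mapping[gene] = op

    degrees = _sample_out_degrees(spec, rng)
    edges: set[tuple[str, str]] = set()
    for reg, d in zip(_reg_names(spec.num_regulators), degrees):
        for j in rng.choice(n_ops, size=int(d), replace=False):
            op = operon_names[j]
            for gene in genes[op]:
                edges.add((reg, gene))
    net = RegulatoryNetwork(edges, name="synth-operon")
    return net, OperonMap(mapping)


def make_saturation_scatter(a: float, b: float, xs: Sequence[float],
                            noise_sd: float = 0.0, seed: int = 0
                            ) -> PartnerTargetSeries:
    """Noisy scatter from y = a(1 - e^(-b x)), truncated at 0.

    Partner counts are nonnegative, so Gaussian noise that would push a
    point below zero is clipped.
    """
    if a < 0 or b < 0 or noise_sd < 0:
        raise ValueError("a, b and noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    x = np.asarray(xs, dtype=float)
    y = a * (1.0 - np.exp(-b * x))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(x))
    y = np.maximum(y, 0.0)
    width = len(str(len(x)))
    ids = tuple(f"x{i + 1:0{width}d}" for i in range(len(x)))
    return PartnerTargetSeries(ids, x, y)
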