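"""Directed regulatory networks and plain-text I/O.

A regulatory network is a directed graph with edges pointing from a
regulator (a transcription factor or kinase) to the gene it controls.
Roles are derived from degree, not declared: any node with out-degree
>= 1 acts as a regulator, any node with in-degree >= 1 as a target, and
a node may hold both roles (a TF that is itself regulated).

The on-disk format is a two-column text file (regulator, target), one
interaction per line, ``#`` comments allowed.  Operon maps are
two-column (gene, operon) files; genes missing from a map are treated
as singleton operons downstream.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO, Union

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryNetwork",
    "OperonMap",
    "NetworkSummary",
    "EdgeListParseError",
    "OperonConflictError",
    "read_edge_list",
    "write_edge_list",
    "read_operon_map",
    "network_summary",
]

Edge = tuple[str, str]
PathLike = Union[str, Path]


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list file."""


class OperonConflictError(ValueError):
    """A gene assigned to more than one operon."""


@dataclass(frozen=True)
class NetworkSummary:
    """Headline sizes: regulators, targets and interactions."""

    num_regulators: int
    num_targets: int
    num_interactions: int


class RegulatoryNetwork:
    """Directed regulator -> target interaction graph.

    Treated as immutable once built: transformation operations return a
    new network.  Adjacency views are cached on first use.

    Parameters
    ----------
    edges :
        Iterable of ``(regulator, target)`` identifier pairs.  Duplicates
        collapse to one edge (set semantics).
    nodes :
        Extra nodes to carry even if they have no incident edge (e.g.
        survivors of edge down-sampling).  Edge endpoints are always
        included.
    name :
        Free-text label used in summaries and file headers.
    """

    def __init__(self, edges: Iterable[Edge] = (), nodes: Iterable[str] = (),
                 name: str = ""):
        self.edges: frozenset[Edge] = frozenset((str(r), str(t)) for r, t in edges)
        node_set = set(nodes)
        for r, t in self.edges:
            node_set.add(r)
            node_set.add(t)
        self.nodes: frozenset[str] = frozenset(node_set)
        self.name = name

    # -- derived structure -------------------------------------------------

    @cached_property
    def out_map(self) -> dict[str, frozenset[str]]:
        """Regulator -> set of its targets."""
        out: dict[str, set[str]] = {}
        for r, t in self.edges:
            out.setdefault(r, set()).add(t)
        return {r: frozenset(ts) for r, ts in out.items()}

    @cached_property
    def in_map(self) -> dict[str, frozenset[str]]:
        """Target -> set of its regulators."""
        inc: dict[str, set[str]] = {}
        for r, t in self.edges:
            inc.setdefault(t, set()).add(r)
        return {t: frozenset(rs) for t, rs in inc.items()}

    @property
    def regulators(self) -> frozenset[str]:
        return frozenset(self.out_map)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(self.in_map)

    def out_degree(self, node: str) -> int:
        return len(self.out_map.get(node, ()))

    def in_degree(self, node: str) -> int:
        return len(self.in_map.get(node, ()))

    def has_self_edges(self) -> bool:
        return any(r == t for r, t in self.edges)

    def summary(self) -> NetworkSummary:
        return NetworkSummary(len(self.out_map), len(self.in_map), len(self.edges))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    # -- dunder ------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self.edges == other.edges and self.nodes == other.nodes

    def __hash__(self) -> int:
        return hash((self.edges, self.nodes))

    def __repr__(self) -> str:
        s = self.summary()
        label = f" {self.name!r}" if self.name else ""
        return (f"<RegulatoryNetwork{label}: {s.num_regulators} regulators, "
                f"{s.num_targets} targets, {s.num_interactions} interactions>")


@dataclass(frozen=True)
class OperonMap:
    """Gene -> operon assignment; unmapped genes are their own operon."""

    gene_to_operon: Mapping[str, str] = field(default_factory=dict)

    def operon_of(self, gene: str) -> str:
        return self.gene_to_operon.get(gene, gene)

    def __len__(self) -> int:
        return len(self.gene_to_operon)


def _iter_lines(source) -> Iterator[tuple[int, str]]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from enumerate(fh, start=1)
        return
    if isinstance(source, io.TextIOBase) or hasattr(source, "read"):
        yield from enumerate(source, start=1)
        return
    # iterable of lines
    yield from enumerate(source, start=1)


def read_edge_list(source, delimiter: str | None = None, header: bool = False,
                   name: str | None = None) -> RegulatoryNetwork:
    """Read a two-column regulator/target edge list.

    Parameters
    ----------
    source :
        Path, open text stream, or iterable of lines.
    delimiter :
        Column separator; ``None`` splits on any whitespace (tab-separated
        files therefore need no special flag).
    header :
        Skip the first non-comment line.
    name :
        Network label; defaults to the file stem for path input.

    Raises
    ------
    EdgeListParseError
        On a line with fewer than two fields (the message names the line).
    ValueError
        On empty input.
    """
    if name is None and isinstance(source, (str, Path)):
        name = Path(source).stem
    edges: set[Edge] = set()
    duplicates = 0
    skipped_header = not header
    for lineno, raw in _iter_lines(source):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not skipped_header:
            skipped_header = True
            continue
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise EdgeListParseError(
                f"line {lineno}: expected >= 2 fields, got {len(fields)}: {line!r}")
        edge = (fields[0].strip(), fields[1].strip())
        if edge in edges:
            duplicates += 1
        else:
            edges.add(edge)
    if not edges:
        raise ValueError("empty edge list: no interactions found")
    if duplicates:
        logger.warning("collapsed %d duplicate edge line(s)", duplicates)
    return RegulatoryNetwork(edges, name=name or "")


def write_edge_list(net: RegulatoryNetwork, sink: Union[PathLike, TextIO]) -> None:
    """Write a network as a two-column TSV, sorted for diffability."""
    lines = "".join(f"{r}\t{t}\n" for r, t in sorted(net.edges))
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(lines, encoding="utf-8")
    else:
        sink.write(lines)


def read_operon_map(source, delimiter: str | None = None) -> OperonMap:
    """Read a two-column (gene, operon) map.

    Raises
    ------
    OperonConflictError
        If a gene appears with two different operon assignments.
    """
    mapping: dict[str, str] = {}
    for lineno, raw in _iter_lines(source):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise EdgeListParseError(
                f"line {lineno}: expected >= 2 fields, got {len(fields)}: {line!r}")
        gene, operon = fields[0].strip(), fields[1].strip()
        if gene in mapping and mapping[gene] != operon:
            raise OperonConflictError(
                f"gene {gene!r} assigned to both {mapping[gene]!r} and {operon!r}")
        mapping[gene] = operon
    return OperonMap(mapping)


def network_summary(net: RegulatoryNetwork) -> NetworkSummary:
    """Regulator / target / interaction counts (Table-1 style)."""
    return net.summary()
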