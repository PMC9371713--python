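"""Directed-network container and plain-text / GraphML I/O.

The edge-list format is one edge per line, two whitespace-separated node
labels (source, target); an optional third numeric column (a weight) is
ignored.  Lines starting with ``#`` are comments; a single-token line
declares an isolated node.  Node labels are opaque strings and are never
coerced to integers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx

__all__ = [
    "DirectedNetwork",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
]


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class DirectedNetwork:
    """A simple directed graph: opaque string node labels, set-valued edges.

    Self-loops ``(v, v)`` are permitted; mutual (bidirectional) connections
    are two directed edges.  Duplicate edges cannot exist (set semantics).
    """

    nodes: frozenset[str] = field(default_factory=frozenset)
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) references undeclared node")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], isolated: Iterable[str] = ()
    ) -> "DirectedNetwork":
        edge_set = frozenset((str(u), str(v)) for u, v in edges)
        node_set = frozenset(str(n) for n in isolated) | frozenset(
            x for e in edge_set for x in e
        )
        return cls(nodes=node_set, edges=edge_set)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.edges

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedNetwork":
        return cls(
            nodes=frozenset(str(n) for n in g.nodes),
            edges=frozenset((str(u), str(v)) for u, v in g.edges),
        )

    def induced_subgraph(self, nodes: Iterable[str]) -> "DirectedNetwork":
        keep = frozenset(nodes)
        if not keep <= self.nodes:
            raise ValueError("induced node set is not a subset of the network")
        return DirectedNetwork(
            nodes=keep,
            edges=frozenset((u, v) for u, v in self.edges if u in keep and v in keep),
        )


def read_edge_list(
    stream: IO[str] | str,
    allow_self_loops: bool = True,
    symmetrize: bool = False,
) -> DirectedNetwork:
    """Parse an edge list into a :class:`DirectedNetwork`.

    Parameters
    ----------
    stream:
        A text stream, or a string holding the file content.
    allow_self_loops:
        When False a line ``v v`` raises :class:`EdgeListParseError`.
    symmetrize:
        Treat the input as undirected: each line adds both directions.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    edges: set[tuple[str, str]] = set()
    isolated: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) == 1:
            isolated.add(tokens[0])
            continue
        u, v = tokens[0], tokens[1]
        if len(tokens) >= 3:
            # third column must be a numeric weight, which we ignore
            try:
                float(tokens[2])
            except ValueError:
                raise EdgeListParseError(
                    f"expected numeric weight in third column, got {tokens[2]!r}",
                    lineno,
                ) from None
        if u == v and not allow_self_loops:
            raise EdgeListParseError(f"self-loop on node {u!r} not allowed", lineno)
        edges.add((u, v))
        if symmetrize and u != v:
            edges.add((v, u))
    return DirectedNetwork.from_edges(edges, isolated=isolated)


def write_edge_list(net: DirectedNetwork, stream: IO[str]) -> None:
    """Write a network as a sorted, reproducible edge list.

    Isolated nodes are written as single-token lines so that
    ``read_edge_list(write_edge_list(net)) == net``.
    """
    touched = {x for e in net.edges for x in e}
    for node in sorted(net.nodes - touched):
        stream.write(f"{node}\n")
    for u, v in sorted(net.edges):
        stream.write(f"{u}\t{v}\n")


def read_graphml(path: str) -> DirectedNetwork:
    g = nx.read_graphml(path)
    if not g.is_directed():
        g = g.to_directed()
    return DirectedNetwork.from_networkx(nx.DiGraph(g))


def write_graphml(net: DirectedNetwork, path: str) -> None:
    nx.write_graphml(net.to_networkx(), path)
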