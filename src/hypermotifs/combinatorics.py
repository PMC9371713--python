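"""Counting and enumerating the ways two motifs can be joined.

Two motifs A (nA nodes) and B (nB nodes) can be joined in two ways:

* **combination** — the motifs share ``Nv`` nodes, with
  ``1 <= Nv <= min(nA, nB) - 1`` so that each motif's topology remains an
  autonomous subgraph of the merged circuit; written ``A{i}*B{j}`` where
  ``{i}``/``{j}`` are the shared positions of each motif;

* **interaction** — the motifs stay disjoint and are linked by at least
  one cross-edge; up to ``2 * nA * nB`` directed links are possible, so
  there are ``2**(2*nA*nB)`` labeled directed interaction topologies
  (``2**(nA*nB)`` undirected), counting the empty set and isomorphic
  duplicates, as the closed-form count does.

Enumeration emits *core topologies*: merged graphs deduplicated up to
isomorphism, quotienting A/B exchange when the two motifs are the same
class.  Extensions add admissible cross-edges to a core.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from hypermotifs.census import MotifClass, canonical_form
from hypermotifs.graphio import DirectedNetwork
from hypermotifs.roles import role_partition

__all__ = [
    "CombinationPattern",
    "InteractionPattern",
    "max_shared_nodes",
    "max_linking_edges",
    "count_interaction_topologies",
    "enumerate_combinations",
    "enumerate_extensions",
    "enumerate_interactions",
]


def max_shared_nodes(n_a: int, n_b: int) -> int:
    """Largest number of nodes two motifs may share: ``min(nA, nB) - 1``.

    Sharing all nodes of the smaller motif would absorb it into the
    larger one, so at least one node of each motif must stay exclusive.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("motifs must have at least 2 nodes to be combined")
    return min(n_a, n_b) - 1


def max_linking_edges(n_a: int, n_b: int, directed: bool = True) -> int:
    """Maximal number of linking edges in an interaction: ``nA*nB`` node
    pairs, doubled for directed networks."""
    if n_a < 1 or n_b < 1:
        raise ValueError("motif sizes must be positive")
    return n_a * n_b * (2 if directed else 1)


def count_interaction_topologies(
    n_a: int, n_b: int, directed: bool = True, nonempty: bool = False
) -> int:
    """Number of labeled interaction topologies between two motifs.

    ``2**(2*nA*nB)`` for directed networks, ``2**(nA*nB)`` undirected.
    This counts raw cross-edge subsets (including isomorphic duplicates);
    ``nonempty=True`` drops the zero-edge case, matching the requirement
    that an interaction has at least one link.  For isomorphism-unique
    counts of actual motif pairs see :func:`enumerate_interactions`.
    """
    total = 2 ** max_linking_edges(n_a, n_b, directed=directed)
    return total - 1 if nonempty else total


# ---------------------------------------------------------------------------
# merged-graph plumbing


def _merged_network(edges: Iterable[tuple[str, str]]) -> DirectedNetwork:
    return DirectedNetwork.from_edges(edges)


def _graph_key(nodes: Sequence[str], edges: set[tuple[str, str]]) -> tuple[int, int]:
    order = list(nodes)
    index = {n: i for i, n in enumerate(order)}
    k = len(order)
    adj = [[0] * k for _ in range(k)]
    for u, v in edges:
        adj[index[u]][index[v]] = 1
    return canonical_form(adj)


def _positions_label(motif: MotifClass, positions: Sequence[int]) -> str:
    labels = role_partition(motif).labels
    part = role_partition(motif)
    return ",".join(labels[part.orbit_of(p)] for p in positions)


@dataclass(frozen=True)
class CombinationPattern:
    """Core topology of two motifs sharing nodes, ``A{i}*B{j}``.

    ``shared_a[t]`` (a position of motif A) is identified with
    ``shared_b[t]``.  Merged-graph nodes are named ``A<i>`` for A's
    positions and ``B<j>`` for B's exclusive positions.
    """

    motif_a: MotifClass
    motif_b: MotifClass
    shared_a: tuple[int, ...]
    shared_b: tuple[int, ...]
    merged: DirectedNetwork
    canonical_key: tuple[int, int]

    @property
    def n_shared(self) -> int:
        return len(self.shared_a)

    @property
    def notation(self) -> str:
        name_a = self.motif_a.display_name or "A"
        name_b = self.motif_b.display_name or "B"
        ia = _positions_label(self.motif_a, self.shared_a)
        jb = _positions_label(self.motif_b, self.shared_b)
        return f"{name_a}{{{ia}}}*{name_b}{{{jb}}}"


def _merge_edges(
    motif_a: MotifClass,
    motif_b: MotifClass,
    shared_a: Sequence[int],
    shared_b: Sequence[int],
) -> tuple[set[tuple[str, str]], list[str]]:
    """Union of both motifs' edges under the shared-node identification."""
    ident = dict(zip(shared_b, shared_a))

    def a_name(i: int) -> str:
        return f"A{i}"

    def b_name(j: int) -> str:
        return a_name(ident[j]) if j in ident else f"B{j}"

    adj_a = motif_a.adjacency
    adj_b = motif_b.adjacency
    edges: set[tuple[str, str]] = set()
    for i in range(motif_a.size):
        for j in range(motif_a.size):
            if adj_a[i, j]:
                edges.add((a_name(i), a_name(j)))
    for i in range(motif_b.size):
        for j in range(motif_b.size):
            if adj_b[i, j]:
                edges.add((b_name(i), b_name(j)))
    nodes = [a_name(i) for i in range(motif_a.size)] + [
        f"B{j}" for j in range(motif_b.size) if j not in ident
    ]
    return edges, nodes


def _contains_as_induced(
    edges: set[tuple[str, str]], motif: MotifClass, node_names: Sequence[str]
) -> bool:
    """Is the motif an *induced* occurrence on its designated merged nodes?

    The merged graph restricted to the motif's node set must carry the
    motif's edges and no others.  Merging two motifs can only violate
    this when the other motif contributes a conflicting edge between
    shared nodes (e.g. identifying an X->Y pair of one FFL with a Y->X
    pair of the other); such identifications are not core topologies.
    """
    adj = motif.adjacency
    names = set(node_names)
    for i in range(motif.size):
        for j in range(motif.size):
            if adj[i, j] and (node_names[i], node_names[j]) not in edges:
                return False
    for u, v in edges:
        if u in names and v in names:
            i, j = node_names.index(u), node_names.index(v)
            if not adj[i, j]:
                return False
    return True


def enumerate_combinations(
    motif_a: MotifClass,
    motif_b: MotifClass,
    with_exclusions: bool = False,
) -> list[CombinationPattern] | tuple[list[CombinationPattern], int]:
    """All core combination topologies of two motifs, deduplicated.

    Every injective identification of ``Nv`` positions of A with ``Nv``
    positions of B (``1 <= Nv <= min-1``) is generated; identifications
    that break the induced-occurrence invariant (one motif would gain a
    conflicting edge between shared nodes) are excluded, and merged
    graphs that are isomorphic are reported once.  When the two motifs
    are the same class, exchanging A and B yields isomorphic merged
    graphs, so that symmetry is quotiented automatically.

    With ``with_exclusions=True`` returns ``(patterns, n_excluded)``.
    """
    if motif_a.size > 4 or motif_b.size > 4:
        raise ValueError("combination enumeration supported for motif sizes <= 4")
    out: list[CombinationPattern] = []
    seen: set[tuple[int, int]] = set()
    excluded = 0
    nv_max = max_shared_nodes(motif_a.size, motif_b.size)
    for nv in range(1, nv_max + 1):
        for sub_a in itertools.combinations(range(motif_a.size), nv):
            for perm_b in itertools.permutations(range(motif_b.size), nv):
                edges, nodes = _merge_edges(motif_a, motif_b, sub_a, perm_b)
                a_nodes = [f"A{i}" for i in range(motif_a.size)]
                ident = dict(zip(perm_b, sub_a))
                b_nodes = [
                    f"A{ident[j]}" if j in ident else f"B{j}"
                    for j in range(motif_b.size)
                ]
                if not (
                    _contains_as_induced(edges, motif_a, a_nodes)
                    and _contains_as_induced(edges, motif_b, b_nodes)
                ):
                    excluded += 1
                    continue
                key = _graph_key(nodes, edges)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    CombinationPattern(
                        motif_a=motif_a,
                        motif_b=motif_b,
                        shared_a=tuple(sub_a),
                        shared_b=tuple(perm_b),
                        merged=_merged_network(edges),
                        canonical_key=key,
                    )
                )
    if with_exclusions:
        return out, excluded
    return out


@dataclass(frozen=True)
class InteractionPattern:
    """Two disjoint motifs linked by cross-edges, ``A{i,j}+B{k,l}``."""

    motif_a: MotifClass
    motif_b: MotifClass
    links: frozenset[tuple[str, str]]  # directed edges between A<i> / B<j> nodes
    merged: DirectedNetwork
    canonical_key: tuple[int, int]

    @property
    def notation(self) -> str:
        name_a = self.motif_a.display_name or "A"
        name_b = self.motif_b.display_name or "B"
        senders_a = sorted({u[1:] for u, v in self.links if u.startswith("A")})
        receivers_a = sorted({v[1:] for u, v in self.links if v.startswith("A")})
        senders_b = sorted({u[1:] for u, v in self.links if u.startswith("B")})
        receivers_b = sorted({v[1:] for u, v in self.links if v.startswith("B")})
        ij = ",".join(senders_a) + ";" + ",".join(receivers_a)
        kl = ",".join(senders_b) + ";" + ",".join(receivers_b)
        return f"{name_a}{{{ij}}}+{name_b}{{{kl}}}"


def _motif_edges(motif: MotifClass, prefix: str) -> set[tuple[str, str]]:
    adj = motif.adjacency
    return {
        (f"{prefix}{i}", f"{prefix}{j}")
        for i in range(motif.size)
        for j in range(motif.size)
        if adj[i, j]
    }


def enumerate_interactions(
    motif_a: MotifClass,
    motif_b: MotifClass,
    max_links: int | None = None,
    max_subsets: int = 1 << 16,
) -> list[InteractionPattern]:
    """Interaction topologies (>= 1 linking edge) deduplicated up to
    isomorphism.

    The raw space is ``2**(2*nA*nB)`` cross-edge subsets; ``max_links``
    bounds the number of links per pattern to keep enumeration tractable
    for larger motif pairs.
    """
    cross = [
        (f"A{i}", f"B{j}") for i in range(motif_a.size) for j in range(motif_b.size)
    ]
    directed_cross = [(u, v) for u, v in cross] + [(v, u) for u, v in cross]
    base = _motif_edges(motif_a, "A") | _motif_edges(motif_b, "B")
    nodes = [f"A{i}" for i in range(motif_a.size)] + [
        f"B{j}" for j in range(motif_b.size)
    ]
    sizes = range(1, (max_links or len(directed_cross)) + 1)
    total = sum(
        len(list(itertools.combinations(directed_cross, s))) for s in sizes
    )
    if total > max_subsets:
        raise ValueError(
            f"{total} cross-edge subsets exceed max_subsets={max_subsets}; "
            "restrict max_links"
        )
    out: list[InteractionPattern] = []
    seen: set[tuple[int, int]] = set()
    for s in sizes:
        for subset in itertools.combinations(directed_cross, s):
            edges = base | set(subset)
            key = _graph_key(nodes, edges)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                InteractionPattern(
                    motif_a=motif_a,
                    motif_b=motif_b,
                    links=frozenset(subset),
                    merged=_merged_network(edges),
                    canonical_key=key,
                )
            )
    return out


def enumerate_extensions(pattern: CombinationPattern) -> list[DirectedNetwork]:
    """All extensions of a core combination topology.

    An extension adds any subset of admissible cross-edges — directed
    edges between node pairs that do not participate in the same motif
    (one node exclusive to A, the other exclusive to B).  The core itself
    (empty subset) is included; results are deduplicated up to
    isomorphism and always contain the core as a subgraph.
    """
    ident_targets = {f"A{i}" for i in pattern.shared_a}
    a_only = [
        f"A{i}" for i in range(pattern.motif_a.size) if i not in pattern.shared_a
    ]
    b_only = sorted(
        n for n in pattern.merged.nodes if n.startswith("B")
    )
    admissible: list[tuple[str, str]] = []
    for u in a_only:
        for v in b_only:
            for e in ((u, v), (v, u)):
                if e not in pattern.merged.edges:
                    admissible.append(e)
    _ = ident_targets  # shared nodes participate in both motifs: never admissible
    nodes = sorted(pattern.merged.nodes)
    core_edges = set(pattern.merged.edges)
    seen: set[tuple[int, int]] = set()
    out: list[DirectedNetwork] = []
    for r in range(len(admissible) + 1):
        for subset in itertools.combinations(admissible, r):
            edges = core_edges | set(subset)
            key = _graph_key(nodes, edges)
            if key in seen:
                continue
            seen.add(key)
            out.append(DirectedNetwork.from_edges(edges))
    return out
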