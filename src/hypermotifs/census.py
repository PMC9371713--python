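"""Connected k-node subgraph census for directed networks.

Canonicalization is exact: the canonical key of a k-node digraph is the
minimum row-major adjacency encoding (diagonal included, so self-loops
are part of the structure) over all k! node permutations.  This is cheap
for the motif sizes that matter here (k <= 4) and needs no heuristic
labeling.

Enumeration uses the ESU algorithm on the weak (undirected) skeleton, so
"connected subgraph" means weakly connected induced subgraph — the
standard motif convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from hypermotifs.graphio import DirectedNetwork

__all__ = [
    "MotifClass",
    "MotifInstanceSet",
    "canonical_form",
    "canonical_order",
    "motif_from_edges",
    "named_motif",
    "NAMED_MOTIFS",
    "enumerate_connected_subgraphs",
    "degree_preserving_randomization",
    "motif_significance",
    "MotifZScore",
]


# ---------------------------------------------------------------------------
# canonical forms


def _encode(adj: Sequence[Sequence[int]], perm: Sequence[int]) -> int:
    """Row-major bit encoding of adj permuted by perm (perm[i] = old index
    placed at new position i)."""
    k = len(perm)
    code = 0
    for i in range(k):
        for j in range(k):
            code = (code << 1) | (1 if adj[perm[i]][perm[j]] else 0)
    return code


def canonical_form(adj: Sequence[Sequence[int]]) -> tuple[int, int]:
    """Canonical key ``(k, code)`` of a k-node digraph adjacency matrix.

    The key is invariant under node relabeling and distinct for
    non-isomorphic digraphs (exact minimization over all permutations).
    """
    k = len(adj)
    if k < 1:
        raise ValueError("graph must have at least one node")
    best = min(_encode(adj, p) for p in itertools.permutations(range(k)))
    return (k, best)


def canonical_order(
    adj: Sequence[Sequence[int]], nodes: Sequence[str]
) -> tuple[tuple[int, int], tuple[str, ...]]:
    """Canonical key plus the unique canonical node tuple.

    Among all permutations achieving the minimal encoding (one per
    automorphism), the node tuple that is lexicographically smallest is
    returned, so every subgraph occurrence has exactly one normal form.
    """
    k = len(adj)
    best_code: int | None = None
    best_perms: list[tuple[int, ...]] = []
    for p in itertools.permutations(range(k)):
        code = _encode(adj, p)
        if best_code is None or code < best_code:
            best_code = code
            best_perms = [p]
        elif code == best_code:
            best_perms.append(p)
    assert best_code is not None
    tup = min(tuple(nodes[p[i]] for i in range(k)) for p in best_perms)
    return (k, best_code), tup


def adjacency_from_key(key: tuple[int, int]) -> np.ndarray:
    """Rebuild the canonical adjacency matrix from a canonical key."""
    k, code = key
    bits = [(code >> (k * k - 1 - t)) & 1 for t in range(k * k)]
    return np.array(bits, dtype=np.int8).reshape(k, k)


@dataclass(frozen=True)
class MotifClass:
    """An isomorphism class of a small connected digraph."""

    size: int
    canonical_key: tuple[int, int]
    display_name: str | None = None

    @property
    def adjacency(self) -> np.ndarray:
        return adjacency_from_key(self.canonical_key)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        name = self.display_name or f"motif-{self.canonical_key[1]}"
        return f"MotifClass({name}, k={self.size})"


@dataclass
class MotifInstanceSet:
    """All occurrences of one motif class, as canonical node tuples."""

    motif: MotifClass
    instances: set[tuple[str, ...]] = field(default_factory=set)

    @property
    def count(self) -> int:
        return len(self.instances)


def motif_from_edges(
    edges: Iterable[tuple[int, int]], size: int, name: str | None = None
) -> MotifClass:
    """Build a MotifClass from integer-position edges on ``range(size)``."""
    adj = [[0] * size for _ in range(size)]
    for u, v in edges:
        adj[u][v] = 1
    return MotifClass(size=size, canonical_key=canonical_form(adj), display_name=name)


# Positions in these prototypes are meaningful: role labels in
# hypermotifs.roles refer to prototype positions.
_NAMED_PROTOTYPES: dict[str, tuple[int, list[tuple[int, int]], list[str]]] = {
    # name: (size, edges on positions, per-position role label)
    "SL": (1, [(0, 0)], ["self"]),
    "edge": (2, [(0, 1)], ["source", "target"]),
    "mutual-dyad": (2, [(0, 1), (1, 0)], ["partner", "partner"]),
    "chain": (3, [(0, 1), (1, 2)], ["input", "intermediate", "output"]),
    "FFL": (3, [(0, 1), (0, 2), (1, 2)], ["input", "intermediate", "output"]),
    "3-loop": (3, [(0, 1), (1, 2), (2, 0)], ["member", "member", "member"]),
    "V-out": (3, [(0, 1), (0, 2)], ["input", "output", "output"]),
    "V-in": (3, [(0, 2), (1, 2)], ["input", "input", "output"]),
}


def named_motif(name: str) -> MotifClass:
    """Look up a built-in motif class by its conventional name."""
    try:
        size, edges, _ = _NAMED_PROTOTYPES[name]
    except KeyError:
        raise KeyError(
            f"unknown motif {name!r}; known: {sorted(_NAMED_PROTOTYPES)}"
        ) from None
    return motif_from_edges(edges, size, name=name)


NAMED_MOTIFS: dict[str, MotifClass] = {}


def _register_named() -> None:
    for name in _NAMED_PROTOTYPES:
        NAMED_MOTIFS[name] = named_motif(name)


_register_named()


def display_name_for_key(key: tuple[int, int]) -> str | None:
    for name, motif in NAMED_MOTIFS.items():
        if motif.canonical_key == key:
            return name
    return None


def prototype_role_labels(name: str) -> list[str]:
    return list(_NAMED_PROTOTYPES[name][2])


# ---------------------------------------------------------------------------
# enumeration (ESU on the weak skeleton)


def _index_network(net: DirectedNetwork):
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    succ: list[set[int]] = [set() for _ in range(n)]
    pred: list[set[int]] = [set() for _ in range(n)]
    for u, v in net.edges:
        succ[idx[u]].add(idx[v])
        pred[idx[v]].add(idx[u])
    skel = [succ[i] | pred[i] - {i} for i in range(n)]
    for i in range(n):
        skel[i].discard(i)
    return nodes, succ, pred, skel


def enumerate_connected_subgraphs(
    net: DirectedNetwork, k: int
) -> dict[tuple[int, int], MotifInstanceSet]:
    """Exact census of weakly-connected induced k-node subgraphs.

    Returns a mapping from canonical key to the set of occurrences; each
    occurrence is a node tuple in canonical role order.
    """
    if k < 2:
        raise ValueError("subgraph size must be at least 2")
    nodes, succ, pred, skel = _index_network(net)
    n = len(nodes)
    if k > n:
        return {}

    result: dict[tuple[int, int], MotifInstanceSet] = {}

    def classify(node_ids: tuple[int, ...]) -> None:
        labels = [nodes[i] for i in node_ids]
        kk = len(node_ids)
        adj = [[0] * kk for _ in range(kk)]
        for a in range(kk):
            sa = succ[node_ids[a]]
            for b in range(kk):
                if node_ids[b] in sa:
                    adj[a][b] = 1
        key, tup = canonical_order(adj, labels)
        entry = result.get(key)
        if entry is None:
            motif = MotifClass(
                size=kk, canonical_key=key, display_name=display_name_for_key(key)
            )
            entry = MotifInstanceSet(motif=motif)
            result[key] = entry
        entry.instances.add(tup)

    # ESU (Wernicke): extension sets restricted to ids greater than the root
    def extend(sub: list[int], ext: set[int], root: int) -> None:
        if len(sub) == k:
            classify(tuple(sub))
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            neigh_sub = set().union(*(skel[x] for x in sub)) | set(sub)
            new_ext = ext | {
                u for u in skel[w] if u > root and u not in neigh_sub and u != w
            }
            sub.append(w)
            extend(sub, new_ext, root)
            sub.pop()

    for v in range(n):
        extend([v], {u for u in skel[v] if u > v}, v)
    return result


def census_counts(net: DirectedNetwork, k: int) -> dict[tuple[int, int], int]:
    """Per-class occurrence counts (convenience over full enumeration)."""
    return {key: s.count for key, s in enumerate_connected_subgraphs(net, k).items()}


# ---------------------------------------------------------------------------
# degree-preserving randomization and motif significance


def degree_preserving_randomization(
    net: DirectedNetwork,
    rng: np.random.Generator | int,
    swaps_per_edge: int = 10,
) -> DirectedNetwork:
    """Randomize by accepted double-edge swaps.

    Per-node in- and out-degrees are preserved exactly.  Swaps that would
    create a duplicate edge or a new self-loop are rejected; existing
    self-loops are left in place (they are never picked for swapping).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    edges = [e for e in net.edges if e[0] != e[1]]
    loops = [e for e in net.edges if e[0] == e[1]]
    m = len(edges)
    if m < 2:
        warnings.warn("network too small to randomize; returning a copy")
        return net
    edge_set = set(edges)
    target = swaps_per_edge * m
    accepted = 0
    attempts = 0
    max_attempts = 200 * target
    while accepted < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == c or b == d:
            continue
        if a == d or c == b:
            continue  # would create a self-loop
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1
    if accepted == 0:
        warnings.warn("no valid edge swaps exist; network is fully constrained")
    return DirectedNetwork(
        nodes=net.nodes, edges=frozenset(edge_set) | frozenset(loops)
    )


@dataclass
class MotifZScore:
    """Observed count of one subgraph class against a randomized ensemble."""

    motif: MotifClass
    count: int
    null_mean: float
    null_sd: float
    z: float
    degenerate: bool = False


def motif_significance(
    net: DirectedNetwork,
    k: int,
    n_random: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> dict[tuple[int, int], MotifZScore]:
    """Score each connected k-node subgraph class against a degree-preserving
    null ensemble (edge switching), MFinder-style.

    A class with zero null variance is reported with ``z = 0`` and
    ``degenerate = True`` rather than an infinite score.
    """
    if n_random < 2:
        raise ValueError("need at least 2 random networks")
    observed = enumerate_connected_subgraphs(net, k)
    samples: list[dict[tuple[int, int], int]] = []
    for i in range(n_random):
        sample = degree_preserving_randomization(
            net, np.random.default_rng(seed + i), swaps_per_edge=swaps_per_edge
        )
        samples.append(census_counts(sample, k))
    keys = set(observed)
    for counts in samples:
        keys |= set(counts)
    out: dict[tuple[int, int], MotifZScore] = {}
    for key in sorted(keys):
        hist = np.asarray([c.get(key, 0) for c in samples], dtype=float)
        obs = observed[key].count if key in observed else 0
        mean = float(hist.mean())
        sd = float(hist.std(ddof=1))
        motif = (
            observed[key].motif
            if key in observed
            else MotifClass(key[0], key, display_name_for_key(key))
        )
        if sd == 0.0:
            out[key] = MotifZScore(motif, obs, mean, 0.0, 0.0, degenerate=True)
        else:
            out[key] = MotifZScore(motif, obs, mean, sd, (obs - mean) / sd)
    return out
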