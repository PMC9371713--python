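"""Motif role categories from automorphism orbits.

Two positions of a motif play the same role exactly when some
automorphism of the motif digraph maps one onto the other.  Roles are
purely structural (unsigned topology); for known motif classes the
orbits carry conventional labels (FFL: input / intermediate / output),
otherwise synthetic labels ``orbit0, orbit1, ...`` are attached.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np

from hypermotifs.census import (
    MotifClass,
    MotifInstanceSet,
    _NAMED_PROTOTYPES,
    canonical_form,
)
from hypermotifs.graphio import DirectedNetwork

__all__ = ["RolePartition", "role_partition", "assign_roles", "RoleAssignment"]


def _automorphisms(adj: np.ndarray) -> list[tuple[int, ...]]:
    k = adj.shape[0]
    autos = []
    for p in itertools.permutations(range(k)):
        if all(adj[p[i], p[j]] == adj[i, j] for i in range(k) for j in range(k)):
            autos.append(p)
    return autos


@dataclass(frozen=True)
class RolePartition:
    """Automorphism orbits of a motif's positions, with optional labels."""

    motif: MotifClass
    orbits: tuple[tuple[int, ...], ...]
    labels: tuple[str, ...]

    def orbit_of(self, position: int) -> int:
        for i, orbit in enumerate(self.orbits):
            if position in orbit:
                return i
        raise ValueError(f"position {position} out of range")

    @property
    def n_roles(self) -> int:
        return len(self.orbits)


def _orbit_labels(motif: MotifClass, orbits: tuple[tuple[int, ...], ...]) -> tuple[str, ...]:
    """Conventional labels for known classes, via a prototype isomorphism."""
    name = motif.display_name
    if name not in _NAMED_PROTOTYPES:
        return tuple(f"orbit{i}" for i in range(len(orbits)))
    size, edges, proto_labels = _NAMED_PROTOTYPES[name]
    proto = np.zeros((size, size), dtype=np.int8)
    for u, v in edges:
        proto[u, v] = 1
    adj = motif.adjacency
    # find a permutation carrying prototype positions onto canonical positions
    for p in itertools.permutations(range(size)):
        if all(
            adj[p[i], p[j]] == proto[i, j] for i in range(size) for j in range(size)
        ):
            canon_label = {p[i]: proto_labels[i] for i in range(size)}
            return tuple(canon_label[orbit[0]] for orbit in orbits)
    return tuple(f"orbit{i}" for i in range(len(orbits)))  # pragma: no cover


def role_partition(motif: MotifClass) -> RolePartition:
    """Partition motif positions into automorphism orbits.

    Exact (exhaustive permutation check); intended for motif sizes <= 4.
    Orbits are ordered by their smallest canonical position.
    """
    if motif.size > 4:
        raise ValueError("exact orbit computation supported for size <= 4 only")
    adj = motif.adjacency
    k = motif.size
    autos = _automorphisms(adj)
    seen: set[int] = set()
    orbits: list[tuple[int, ...]] = []
    for pos in range(k):
        if pos in seen:
            continue
        orbit = sorted({p[pos] for p in autos} | {pos})
        # orbit closure: p[pos] for automorphism p written as "new <- old" is
        # symmetric under the group, so the set above is already the orbit
        seen.update(orbit)
        orbits.append(tuple(orbit))
    orbits_t = tuple(orbits)
    return RolePartition(motif=motif, orbits=orbits_t, labels=_orbit_labels(motif, orbits_t))


@dataclass
class RoleAssignment:
    """Occupancy of one motif role by network nodes.

    ``multiset`` counts, per node, the number of motif instances in which
    the node plays this role; ``nodes`` is the deduplicated set used for
    Jaccard overlaps.
    """

    motif: MotifClass
    orbit_index: int
    label: str
    multiset: Counter

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.multiset)


def assign_roles(
    net: DirectedNetwork, instance_set: MotifInstanceSet
) -> dict[int, RoleAssignment]:
    """Map each role orbit of a motif to the nodes occupying it.

    Instances must be canonical node tuples from the census of ``net``:
    position ``i`` of an instance tuple occupies canonical position ``i``
    of the motif.
    """
    partition = role_partition(instance_set.motif)
    counters: dict[int, Counter] = {i: Counter() for i in range(partition.n_roles)}
    succ: dict[str, set[str]] = {}
    for u, v in net.edges:
        succ.setdefault(u, set()).add(v)
    motif_adj = instance_set.motif.adjacency
    k = instance_set.motif.size
    for inst in instance_set.instances:
        adj = [
            [1 if inst[j] in succ.get(inst[i], ()) else 0 for j in range(k)]
            for i in range(k)
        ]
        if canonical_form(adj) != instance_set.motif.canonical_key:
            raise ValueError(
                f"instance {inst} is not an occurrence of {instance_set.motif}"
            )
        # the canonical tuple realizes the canonical adjacency directly
        if any(
            adj[i][j] != motif_adj[i, j] for i in range(k) for j in range(k)
        ):
            raise ValueError(f"instance {inst} is not in canonical position order")
        for orbit_i, orbit in enumerate(partition.orbits):
            for pos in orbit:
                counters[orbit_i][inst[pos]] += 1
    return {
        i: RoleAssignment(
            motif=instance_set.motif,
            orbit_index=i,
            label=partition.labels[i],
            multiset=counters[i],
        )
        for i in range(partition.n_roles)
    }
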