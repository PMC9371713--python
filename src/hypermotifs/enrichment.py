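"""Detection of enriched motif combinations in directed networks.

Pipeline: identify the network's motif classes, assign every
motif-participating node to a role (automorphism orbit), measure the
Jaccard overlap between every pair of role node-sets (and, on the
diagonal, the fraction of nodes repeating within a role), and compare
each statistic to an ensemble of randomized networks that preserve the
node count, edge count, per-node in/out degrees and the *entire* census
of connected subgraphs up to three nodes.  Overlaps that survive
Benjamini-Hochberg correction (q < alpha) are called over- or
underrepresented by the sign of their Z-score.

The census-preserving null is produced by a Metropolis random walk of
degree-preserving double-edge swaps whose energy is the L1 distance
between the walker's 3-node census vector and the original's: a thermal
exploration phase reshuffles edge placement while staying near the
zero-distance manifold, and a closing simulated-annealing phase
(geometric cooling) returns the walker to census distance exactly zero.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from hypermotifs.census import (
    MotifClass,
    canonical_form,
    enumerate_connected_subgraphs,
    motif_significance,
)
from hypermotifs.graphio import DirectedNetwork
from hypermotifs.roles import RoleAssignment, assign_roles

__all__ = [
    "EnrichmentRecord",
    "jaccard_overlap",
    "same_role_repetition",
    "randomize_preserving_census",
    "detect_hypermotifs",
]


def jaccard_overlap(set_i: Iterable[str], set_j: Iterable[str]) -> float:
    """Jaccard index |i ∩ j| / |i ∪ j| of two node sets."""
    si, sj = set(set_i), set(set_j)
    union = si | sj
    if not union:
        raise ValueError("Jaccard overlap of two empty sets is undefined")
    return len(si & sj) / len(union)


def same_role_repetition(multiset: Counter) -> float:
    """Fraction of a role's nodes that occupy the role more than once.

    This is the diagonal statistic: it measures how often the *same*
    motif class reuses a node in the *same* role (e.g. one regulator
    serving as the input of many feedforward loops).
    """
    if not multiset:
        raise ValueError("repetition fraction of an empty role is undefined")
    repeated = sum(1 for _, c in multiset.items() if c > 1)
    return repeated / len(multiset)


# ---------------------------------------------------------------------------
# triple-classification lookup table
#
# A 3-node induced subgraph is encoded in 9 bits: 6 off-diagonal edge bits
# plus 3 self-loop bits.  The table maps each code to a dense class index;
# disconnected triples map to the sentinel index (last).

_LUT_CODES = 512


def _build_lut() -> tuple[np.ndarray, list[tuple[int, int]], int]:
    key_to_idx: dict[tuple[int, int], int] = {}
    keys: list[tuple[int, int]] = []
    lut = np.zeros(_LUT_CODES, dtype=np.int32)
    for code in range(_LUT_CODES):
        bits = [(code >> t) & 1 for t in range(9)]
        e_ij, e_ji, e_ik, e_ki, e_jk, e_kj, d_i, d_j, d_k = bits
        adj = [[d_i, e_ij, e_ik], [e_ji, d_j, e_jk], [e_ki, e_kj, d_k]]
        # a triple is weakly connected iff at least 2 of its 3 node pairs
        # are linked (with only one link, one node is isolated)
        n_links = (e_ij | e_ji) + (e_ik | e_ki) + (e_jk | e_kj)
        if n_links < 2:
            lut[code] = -1
            continue
        key = canonical_form(adj)
        if key not in key_to_idx:
            key_to_idx[key] = len(keys)
            keys.append(key)
        lut[code] = key_to_idx[key]
    sentinel = len(keys)
    lut[lut == -1] = sentinel
    return lut, keys, sentinel


_TRIPLE_LUT, _TRIPLE_KEYS, _TRIPLE_SENTINEL = _build_lut()
_KEY_TO_IDX = {k: i for i, k in enumerate(_TRIPLE_KEYS)}


class _AnnealState:
    """Mutable adjacency + census state used by the annealer."""

    def __init__(self, net: DirectedNetwork):
        self.nodes = sorted(net.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.n = n
        self.adj = np.zeros((n, n), dtype=np.uint8)
        loops = []
        swappable = []
        for u, v in net.edges:
            iu, iv = self.index[u], self.index[v]
            self.adj[iu, iv] = 1
            if iu == iv:
                loops.append((iu, iv))
            else:
                swappable.append((iu, iv))
        self.loops = loops
        self.edges = swappable
        self.diag = np.ascontiguousarray(np.diag(self.adj)).astype(np.uint8)

    def census_vector(self) -> np.ndarray:
        """Connected 3-node class counts via skeleton triangle/path scan."""
        n = self.n
        a = self.adj
        skel = ((a + a.T) > 0).astype(np.uint8)
        np.fill_diagonal(skel, 0)
        counts = np.zeros(len(_TRIPLE_KEYS) + 1, dtype=np.int64)
        neighbors = [np.flatnonzero(skel[i]) for i in range(n)]
        seen: set[tuple[int, int, int]] = set()
        for j in range(n):
            nb = neighbors[j]
            for ii in range(len(nb)):
                for kk in range(ii + 1, len(nb)):
                    i, k = int(nb[ii]), int(nb[kk])
                    t = tuple(sorted((i, j, k)))
                    if t in seen:
                        continue
                    seen.add(t)
                    code = self._code(*t)
                    counts[_TRIPLE_LUT[code]] += 1
        return counts[:-1]

    def _code(self, i: int, j: int, k: int) -> int:
        a = self.adj
        return (
            int(a[i, j])
            | (int(a[j, i]) << 1)
            | (int(a[i, k]) << 2)
            | (int(a[k, i]) << 3)
            | (int(a[j, k]) << 4)
            | (int(a[k, j]) << 5)
            | (int(a[i, i]) << 6)
            | (int(a[j, j]) << 7)
            | (int(a[k, k]) << 8)
        )

    def _affected_class_counts(self, u1: int, v1: int, u2: int, v2: int) -> np.ndarray:
        """Class counts over triples whose class a (u1,v1)/(u2,v2) ->
        (u1,v2)/(u2,v1) swap can change.

        The swap only touches edge slots among the unordered pairs
        (u1,v1), (u2,v2), (u1,v2), (u2,v1); a triple can change class
        only if it contains one of them.  The class lookup is invariant
        under the order of the triple, so the codes can be formed with
        the pair first and the outside node last.  Triples inside
        {u1,v1,u2,v2} are added separately (each exactly once).
        """
        a = self.adj
        d = self.diag
        counts = np.zeros(len(_TRIPLE_KEYS) + 1, dtype=np.int64)
        s = (u1, v1, u2, v2)
        mask = np.ones(self.n, dtype=bool)
        mask[list(s)] = False
        w = np.flatnonzero(mask)
        if w.size:
            us = np.array([u1, u2, u1, u2])[:, None]
            vs = np.array([v1, v2, v2, v1])[:, None]
            ww = w[None, :]
            code = (
                a[us, vs].astype(np.int64)
                | (a[vs, us].astype(np.int64) << 1)
                | (a[us, ww].astype(np.int64) << 2)
                | (a[ww, us].astype(np.int64) << 3)
                | (a[vs, ww].astype(np.int64) << 4)
                | (a[ww, vs].astype(np.int64) << 5)
                | (d[us].astype(np.int64) << 6)
                | (d[vs].astype(np.int64) << 7)
                | (d[ww].astype(np.int64) << 8)
            )
            counts += np.bincount(
                _TRIPLE_LUT[code.ravel()], minlength=len(counts)
            ).astype(np.int64)
        for t in itertools.combinations(s, 3):
            counts[_TRIPLE_LUT[self._code(*t)]] += 1
        return counts

    def to_network(self) -> DirectedNetwork:
        edges = [
            (self.nodes[u], self.nodes[v]) for u, v in self.edges
        ] + [(self.nodes[u], self.nodes[v]) for u, v in self.loops]
        return DirectedNetwork(nodes=frozenset(self.nodes), edges=frozenset(edges))


class CensusAnnealError(RuntimeError):
    """Annealing failed to restore the subgraph census within budget."""


def _metropolis_swap(
    state: _AnnealState,
    target: np.ndarray,
    current: np.ndarray,
    energy: int,
    temp: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, bool]:
    """Propose one double-edge swap; Metropolis-accept on the census-distance
    change.  Returns (census vector, energy, accepted)."""
    edges = state.edges
    a = state.adj
    m = len(edges)
    i, j = rng.integers(0, m, size=2)
    if i == j:
        return current, energy, False
    u1, v1 = edges[i]
    u2, v2 = edges[j]
    if len({u1, v1, u2, v2}) < 4:
        return current, energy, False
    if a[u1, v2] or a[u2, v1]:
        return current, energy, False
    before = state._affected_class_counts(u1, v1, u2, v2)
    a[u1, v1] = 0
    a[u2, v2] = 0
    a[u1, v2] = 1
    a[u2, v1] = 1
    after = state._affected_class_counts(u1, v1, u2, v2)
    new = current + (after[:-1] - before[:-1])
    new_energy = int(np.abs(new - target).sum())
    d_e = new_energy - energy
    if d_e <= 0 or rng.random() < math.exp(-d_e / temp):
        edges[i] = (u1, v2)
        edges[j] = (u2, v1)
        return new, new_energy, True
    a[u1, v2] = 0
    a[u2, v1] = 0
    a[u1, v1] = 1
    a[u2, v2] = 1
    return current, energy, False


def _census_preserving_sample(
    net: DirectedNetwork,
    target: np.ndarray,
    rng: np.random.Generator,
    explore_swaps_per_edge: int,
    t_explore: float,
    max_anneal_steps: int,
) -> DirectedNetwork | None:
    """One sample: thermal walk near the census-preserving manifold, then
    simulated annealing back to census distance zero.

    The walk starts from the original network (distance 0), so Metropolis
    excursions stay small and the closing anneal is short; edge placement
    is nevertheless thoroughly reshuffled (the walk accepts thousands of
    swaps on typical inputs).
    """
    state = _AnnealState(net)
    current = target.copy()
    energy = 0
    n_explore = explore_swaps_per_edge * max(len(state.edges), 1)
    for _ in range(n_explore):
        current, energy, _ = _metropolis_swap(
            state, target, current, energy, t_explore, rng
        )
    for step in range(max_anneal_steps):
        if energy == 0:
            return state.to_network()
        temp = max(0.05, 0.3 * (0.9999 ** step))
        current, energy, _ = _metropolis_swap(
            state, target, current, energy, temp, rng
        )
    return state.to_network() if energy == 0 else None


def randomize_preserving_census(
    net: DirectedNetwork,
    max_k: int = 3,
    seed: int = 0,
    ensemble_size: int = 100,
    explore_swaps_per_edge: int = 6,
    t_explore: float = 0.6,
    max_anneal_steps: int = 100_000,
    max_retries: int = 4,
) -> list[DirectedNetwork]:
    """Random networks preserving degrees and the full 3-node census.

    Each sample keeps N, E, every node's in/out degree, self-loops and
    the count of every connected <= 3-node subgraph class equal to the
    original's, while reshuffling edge placement.  Samples are produced
    independently with seeds derived from ``seed + i``.
    """
    if max_k != 3:
        raise ValueError("census preservation implemented for max_k = 3 only")
    target = _AnnealState(net).census_vector()
    samples: list[DirectedNetwork] = []
    for i in range(ensemble_size):
        sample = None
        for retry in range(max_retries):
            rng = np.random.default_rng((seed + i) * max_retries + retry)
            sample = _census_preserving_sample(
                net, target, rng, explore_swaps_per_edge, t_explore, max_anneal_steps
            )
            if sample is not None:
                break
        if sample is None:
            raise CensusAnnealError(
                f"sample {i}: annealing failed to reach census distance 0 in "
                f"{max_retries} retries of {max_anneal_steps} steps "
                f"(N={net.n_nodes}, E={net.n_edges})"
            )
        samples.append(sample)
    return samples


# ---------------------------------------------------------------------------
# the detection pipeline


@dataclass
class EnrichmentRecord:
    """Enrichment statistics for one motif-role pair.

    Diagonal records (``role_i == role_j``) carry the same-role
    repetition fraction instead of a Jaccard index.
    """

    role_i: tuple[MotifClass, int, str]
    role_j: tuple[MotifClass, int, str]
    jaccard: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    q: float
    call: str  # "over" | "under" | "none"
    degenerate: bool = False

    @property
    def is_diagonal(self) -> bool:
        return self.role_i == self.role_j


def _role_table(
    net: DirectedNetwork, motif_classes: Sequence[MotifClass]
) -> dict[tuple[tuple[int, int], int], RoleAssignment]:
    """Role assignments for the designated motif classes, keyed by
    (motif canonical key, orbit index).  Roles with no occupants are
    present with empty multisets."""
    by_size: dict[int, dict] = {}
    for k in sorted({m.size for m in motif_classes}):
        by_size[k] = enumerate_connected_subgraphs(net, k)
    table: dict[tuple[tuple[int, int], int], RoleAssignment] = {}
    for motif in motif_classes:
        found = by_size[motif.size].get(motif.canonical_key)
        if found is None:
            from hypermotifs.census import MotifInstanceSet

            found = MotifInstanceSet(motif=motif)
        assignments = assign_roles(net, found)
        for orbit_i, assignment in assignments.items():
            table[(motif.canonical_key, orbit_i)] = assignment
    return table


def _statistic(
    table: dict[tuple[tuple[int, int], int], RoleAssignment],
    ri: tuple[tuple[int, int], int],
    rj: tuple[tuple[int, int], int],
) -> float | None:
    """Off-diagonal: Jaccard of role node sets; diagonal: repetition
    fraction.  None when undefined (empty sets)."""
    if ri == rj:
        ms = table[ri].multiset
        if not ms:
            return None
        return same_role_repetition(ms)
    si, sj = table[ri].nodes, table[rj].nodes
    if not (si | sj):
        return None
    return jaccard_overlap(si, sj)


def detect_hypermotifs(
    net: DirectedNetwork,
    n_random: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    motif_classes: Sequence[MotifClass] | None = None,
    motif_z_threshold: float = 2.0,
    motif_null_size: int = 20,
    explore_swaps_per_edge: int = 6,
    max_anneal_steps: int = 400_000,
) -> list[EnrichmentRecord]:
    """Detect over/underrepresented combinations of network motifs.

    When ``motif_classes`` is None the network's motifs are auto-called:
    connected 2- and 3-node classes with Z > ``motif_z_threshold``
    against a degree-preserving edge-switching null of
    ``motif_null_size`` samples.  One record is produced per unordered
    role pair plus one diagonal record per role; p-values are one-sided
    normal tails in the direction of Z, corrected jointly by
    Benjamini-Hochberg; q < alpha calls "over" (Z > 0) or "under"
    (Z < 0).
    """
    if n_random < 2:
        raise ValueError("need at least 2 census-preserving random networks")
    if motif_classes is None:
        called: list[MotifClass] = []
        for k in (2, 3):
            for key, score in motif_significance(
                net, k, n_random=motif_null_size, seed=seed
            ).items():
                if not score.degenerate and score.z > motif_z_threshold:
                    called.append(score.motif)
        motif_classes = called
    if not motif_classes:
        raise ValueError("no motif classes designated and none auto-detected")

    table = _role_table(net, motif_classes)
    role_keys = sorted(table)
    pairs = [
        (ri, rj)
        for a_i, ri in enumerate(role_keys)
        for rj in role_keys[a_i:]
    ]
    observed = {pair: _statistic(table, *pair) for pair in pairs}

    ensemble = randomize_preserving_census(
        net,
        max_k=3,
        seed=seed,
        ensemble_size=n_random,
        explore_swaps_per_edge=explore_swaps_per_edge,
        max_anneal_steps=max_anneal_steps,
    )
    null_values: dict[tuple, list[float]] = {pair: [] for pair in pairs}
    for sample in ensemble:
        sample_table = _role_table(sample, motif_classes)
        for pair in pairs:
            v = _statistic(sample_table, *pair)
            if v is not None:
                null_values[pair].append(v)

    motif_by_key = {m.canonical_key: m for m in motif_classes}

    records: list[EnrichmentRecord] = []
    stats: list[tuple[int, float]] = []  # (record index, p) for BH
    for pair in pairs:
        ri, rj = pair
        obs = observed[pair]
        nulls = np.asarray(null_values[pair], dtype=float)
        role_i = (motif_by_key[ri[0]], ri[1], table[ri].label)
        role_j = (motif_by_key[rj[0]], rj[1], table[rj].label)
        if obs is None or nulls.size < 2:
            records.append(
                EnrichmentRecord(
                    role_i, role_j, float("nan"), float("nan"), float("nan"),
                    0.0, float("nan"), float("nan"), "none", degenerate=True,
                )
            )
            continue
        mean = float(nulls.mean())
        sd = float(nulls.std(ddof=1))
        if sd == 0.0:
            records.append(
                EnrichmentRecord(
                    role_i, role_j, float(obs), mean, 0.0, 0.0,
                    float("nan"), float("nan"), "none", degenerate=True,
                )
            )
            continue
        z = (float(obs) - mean) / sd
        p = float(norm.sf(z)) if z > 0 else float(norm.cdf(z))
        records.append(
            EnrichmentRecord(
                role_i, role_j, float(obs), mean, sd, z, p, float("nan"), "none"
            )
        )
        stats.append((len(records) - 1, p))

    if stats:
        idxs, pvals = zip(*stats)
        reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for idx, q, rej in zip(idxs, qvals, reject):
            rec = records[idx]
            rec.q = float(q)
            if rej:
                rec.call = "over" if rec.z > 0 else "under"
    return records
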