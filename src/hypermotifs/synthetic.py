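"""Synthetic directed networks with planted motifs and hypermotifs.

Benchmark generator for the detection pipeline: a uniform random simple
digraph background plus a controlled number of planted motif instances
or combination patterns, with a manifest recording the ground truth so
recovery can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from hypermotifs.census import MotifClass, canonical_order
from hypermotifs.combinatorics import CombinationPattern
from hypermotifs.graphio import DirectedNetwork

__all__ = [
    "PlantingSpec",
    "Planting",
    "PlantedInstance",
    "PlantingManifest",
    "generate_background",
    "plant",
    "generate_planted_network",
]


def generate_background(
    n: int, m: int, seed: int, allow_self_loops: bool = False
) -> DirectedNetwork:
    """Uniform random simple digraph with exactly ``n`` nodes, ``m`` edges.

    Self-loops are excluded by default (most real networks analyzed for
    motifs forbid them; transcription networks are the exception).
    """
    max_edges = n * n if allow_self_loops else n * (n - 1)
    if m < 0 or m > max_edges:
        raise ValueError(f"cannot place {m} edges on {n} nodes (max {max_edges})")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(max_edges, size=m, replace=False)
    width = max(3, len(str(n - 1)))
    labels = [f"v{idx:0{width}d}" for idx in range(n)]
    edges = []
    for c in chosen:
        u, rem = divmod(int(c), n if allow_self_loops else n - 1)
        if allow_self_loops:
            v = rem
        else:
            v = rem if rem < u else rem + 1
        edges.append((labels[u], labels[v]))
    return DirectedNetwork.from_edges(edges, isolated=labels)


@dataclass(frozen=True)
class Planting:
    """One planting directive: a pattern and how many copies to insert.

    ``reuse="fresh"`` creates new nodes per copy; ``reuse="background"``
    wires each copy onto randomly chosen existing nodes (chosen so that
    no edge already runs among them), which leaves the planted nodes
    with background degrees on top of the pattern — the realistic
    benchmark for the detection pipeline, since the null model then has
    freedom over which nodes host the motifs.
    """

    pattern: MotifClass | CombinationPattern
    copies: int
    reuse: str = "fresh"


@dataclass
class PlantingSpec:
    n_nodes: int | None = None
    n_edges: int | None = None
    plantings: list[Planting] = field(default_factory=list)


@dataclass(frozen=True)
class PlantedInstance:
    """Ground truth for one planted motif occurrence (canonical order)."""

    motif_key: tuple[int, int]
    nodes: tuple[str, ...]


@dataclass
class PlantingManifest:
    instances: list[PlantedInstance] = field(default_factory=list)

    def by_motif(self, key: tuple[int, int]) -> list[PlantedInstance]:
        return [inst for inst in self.instances if inst.motif_key == key]


def _pattern_pieces(
    pattern: MotifClass | CombinationPattern,
) -> tuple[list[str], list[tuple[str, str]], list[tuple[tuple[int, int], list[str]]]]:
    """Template nodes, edges and per-motif instance node lists for a pattern."""
    if isinstance(pattern, MotifClass):
        names = [f"A{i}" for i in range(pattern.size)]
        adj = pattern.adjacency
        edges = [
            (names[i], names[j])
            for i in range(pattern.size)
            for j in range(pattern.size)
            if adj[i, j]
        ]
        return names, edges, [(pattern.canonical_key, names)]
    ident = dict(zip(pattern.shared_b, pattern.shared_a))
    a_names = [f"A{i}" for i in range(pattern.motif_a.size)]
    b_names = [
        f"A{ident[j]}" if j in ident else f"B{j}"
        for j in range(pattern.motif_b.size)
    ]
    nodes = sorted(pattern.merged.nodes)
    edges = sorted(pattern.merged.edges)
    return (
        nodes,
        edges,
        [
            (pattern.motif_a.canonical_key, a_names),
            (pattern.motif_b.canonical_key, b_names),
        ],
    )


def _normalize_instance(
    key: tuple[int, int], nodes: Sequence[str], edges: set[tuple[str, str]]
) -> tuple[str, ...]:
    """Canonical node tuple of an occurrence, as the census would report it."""
    k = len(nodes)
    adj = [[1 if (nodes[i], nodes[j]) in edges else 0 for j in range(k)] for i in range(k)]
    got, tup = canonical_order(adj, list(nodes))
    if got != key:
        raise AssertionError("planted subgraph does not realize its motif class")
    return tup


def plant(
    net: DirectedNetwork, spec: PlantingSpec, seed: int
) -> tuple[DirectedNetwork, PlantingManifest]:
    """Insert the spec's planted patterns into a network.

    The default ``fresh`` policy creates brand-new nodes per copy so that
    no accidental motif occurrences arise; the ``background`` policy
    consumes isolated background nodes (error once exhausted), stressing
    the pipeline with plantings embedded among background edges.
    """
    rng = np.random.default_rng(seed)
    edges = set(net.edges)
    all_nodes = set(net.nodes)
    node_pool = sorted(all_nodes)
    manifest = PlantingManifest()
    fresh_counter = 0
    max_attempts = 1000
    for planting in spec.plantings:
        template_nodes, template_edges, motif_instances = _pattern_pieces(
            planting.pattern
        )
        for _ in range(planting.copies):
            if planting.reuse == "fresh":
                mapping = {}
                for t in template_nodes:
                    mapping[t] = f"plant{fresh_counter:04d}_{t}"
                fresh_counter += 1
            elif planting.reuse == "background":
                if len(node_pool) < len(template_nodes):
                    raise ValueError(
                        "node budget exhausted: pattern larger than the network"
                    )
                mapping = None
                for _attempt in range(max_attempts):
                    idx = rng.choice(
                        len(node_pool), size=len(template_nodes), replace=False
                    )
                    chosen = [node_pool[i] for i in idx]
                    # require a clean slate among the chosen nodes so the
                    # planted occurrence is exactly the pattern (induced)
                    if any(
                        (u, v) in edges
                        for u in chosen
                        for v in chosen
                        if u != v
                    ):
                        continue
                    mapping = dict(zip(template_nodes, chosen))
                    break
                if mapping is None:
                    raise ValueError(
                        "node budget exhausted: no edge-free node set found "
                        f"for planting after {max_attempts} attempts"
                    )
            else:
                raise ValueError(f"unknown reuse policy {planting.reuse!r}")
            new_edges = {(mapping[u], mapping[v]) for u, v in template_edges}
            edges |= new_edges
            all_nodes |= set(mapping.values())
            for key, inst_nodes in motif_instances:
                tup = _normalize_instance(
                    key, [mapping[t] for t in inst_nodes], new_edges
                )
                manifest.instances.append(PlantedInstance(motif_key=key, nodes=tup))
    return (
        DirectedNetwork(nodes=frozenset(all_nodes), edges=frozenset(edges)),
        manifest,
    )


def generate_planted_network(
    n: int,
    m: int,
    plantings: list[Planting],
    seed: int,
) -> tuple[DirectedNetwork, PlantingManifest]:
    """Background plus plantings in one call (seed drives both stages)."""
    background = generate_background(n, m, seed)
    return plant(background, PlantingSpec(plantings=plantings), seed + 1)
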