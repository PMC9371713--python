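"""Neighborhood random-walk downsampling of large directed networks.

A walk of ``sz`` steps grows a node sample: each new entry is a random
neighbor of the previous entry with probability 0.85, otherwise a random
neighbor of the current anchor node.  The walk is split into thirds; at
each third boundary the sampler checks whether enough *unique* nodes
have been collected (half the boundary index after the first third, the
full boundary index after the second) and re-anchors at a fresh random
node when the walk is stuck revisiting the same neighborhood.  The
result is the induced subgraph on the unique sampled nodes.

"Neighborhood" is the union of in- and out-neighbors: the sampler's job
is coverage and connectivity, for which edge direction is irrelevant.
"""

from __future__ import annotations

import numpy as np

from hypermotifs.graphio import DirectedNetwork

__all__ = ["downsample"]


def downsample(
    net: DirectedNetwork,
    sz: int,
    seed: int,
    p_continue: float = 0.85,
    max_anchor_retries: int = 100,
) -> DirectedNetwork:
    """Sample an induced subnetwork of at most ``sz`` unique nodes.

    Deterministic given (net, sz, seed).  Raises ``ValueError`` on an
    empty network or ``sz < 3``, and ``RuntimeError`` if no anchor with a
    nonempty neighborhood can be found.
    """
    if sz < 3:
        raise ValueError("target size must be at least 3")
    if not net.nodes:
        raise ValueError("cannot downsample an empty network")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    neigh: dict[str, list[str]] = {n: set() for n in nodes}
    for u, v in net.edges:
        if u != v:
            neigh[u].add(v)
            neigh[v].add(u)
    neigh = {n: sorted(s) for n, s in neigh.items()}

    def random_anchor() -> str:
        for _ in range(max_anchor_retries):
            cand = nodes[int(rng.integers(len(nodes)))]
            if neigh[cand]:
                return cand
        raise RuntimeError("no node with a nonempty neighborhood found")

    def step_from(prev: str, anchor: str) -> str:
        pool = neigh[prev] if rng.random() < p_continue else neigh[anchor]
        if not pool:
            pool = neigh[anchor]
        return pool[int(rng.integers(len(pool)))]

    anchor = random_anchor()
    walk = [anchor]
    walk.append(neigh[anchor][int(rng.integers(len(neigh[anchor])))])
    third = sz // 3
    for i in range(2, sz + 1):
        unique = set(walk)
        if len(unique) >= sz:
            break
        if i == third + 1 and len(unique) < third // 2:
            anchor = random_anchor()
        elif i == 2 * third + 1 and len(unique) < third:
            anchor = random_anchor()
        walk.append(step_from(walk[-1], anchor))
    sampled = set(walk)
    if len(sampled) > sz:  # pragma: no cover - loop breaks before exceeding sz
        sampled = set(walk[: sz])
    return net.induced_subgraph(sampled)
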