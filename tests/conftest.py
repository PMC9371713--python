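"""Shared fixtures: tiny hand-built networks and planted benchmarks."""

from __future__ import annotations

import numpy as np
import pytest

from hypermotifs.census import named_motif
from hypermotifs.combinatorics import enumerate_combinations
from hypermotifs.graphio import DirectedNetwork
from hypermotifs.synthetic import Planting, generate_planted_network


@pytest.fixture(scope="session")
def ffl_net() -> DirectedNetwork:
    """A single feedforward loop X -> Y, X -> Z, Y -> Z."""
    return DirectedNetwork.from_edges([("X", "Y"), ("X", "Z"), ("Y", "Z")])


@pytest.fixture(scope="session")
def cycle_net() -> DirectedNetwork:
    return DirectedNetwork.from_edges([("X", "Y"), ("Y", "Z"), ("Z", "X")])


@pytest.fixture(scope="session")
def ffl_cascade_pattern():
    """The FFL{output}*FFL{input} core topology (output of one FFL is the
    input of the next)."""
    ffl = named_motif("FFL")
    for pattern in enumerate_combinations(ffl, ffl):
        if pattern.notation == "FFL{output}*FFL{input}":
            return pattern
    raise AssertionError("cascade pattern not found")


@pytest.fixture(scope="session")
def planted_net(ffl_cascade_pattern):
    """Sparse random background plus 40 FFL cascades planted onto
    background nodes, with the ground-truth manifest."""
    net, manifest = generate_planted_network(
        n=200,
        m=300,
        plantings=[Planting(ffl_cascade_pattern, 40, reuse="background")],
        seed=11,
    )
    return net, manifest


@pytest.fixture(scope="session")
def background_net() -> DirectedNetwork:
    """The same background family with nothing planted."""
    from hypermotifs.synthetic import generate_background

    return generate_background(200, 300, seed=11)


def random_network(n: int, m: int, seed: int) -> DirectedNetwork:
    """Uniform simple digraph used by oracle comparisons."""
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    idx = rng.choice(len(pairs), size=min(m, len(pairs)), replace=False)
    labels = [f"n{i:03d}" for i in range(n)]
    return DirectedNetwork.from_edges(
        [(labels[pairs[i][0]], labels[pairs[i][1]]) for i in idx], isolated=labels
    )
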