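"""Canonical forms, subgraph enumeration and degree-preserving nulls.

The enumeration oracle is a brute-force scan of all node triples; the
canonicalization oracle is the permutation orbit of the labeled
adjacency encodings.
"""

import itertools
from collections import Counter

import numpy as np
import pytest

from hypermotifs.census import (
    canonical_form,
    canonical_order,
    census_counts,
    degree_preserving_randomization,
    enumerate_connected_subgraphs,
    motif_from_edges,
    motif_significance,
    named_motif,
)
from hypermotifs.graphio import DirectedNetwork
from hypermotifs.synthetic import Planting, generate_planted_network

from conftest import random_network


def brute_force_triads(net: DirectedNetwork) -> dict:
    """Oracle: classify every weakly-connected induced triple directly."""
    nodes = sorted(net.nodes)
    succ = {n: set() for n in nodes}
    for u, v in net.edges:
        succ[u].add(v)
    counts: Counter = Counter()
    for trip in itertools.combinations(nodes, 3):
        adj = [[1 if trip[j] in succ[trip[i]] else 0 for j in range(3)] for i in range(3)]
        linked = sum(
            1
            for a, b in itertools.combinations(range(3), 2)
            if adj[a][b] or adj[b][a]
        )
        if linked < 2:
            continue
        counts[canonical_form(adj)] += 1
    return dict(counts)


class TestCanonicalForm:
    def test_isomorphism_invariance_ffl(self):
        a = motif_from_edges([(0, 1), (0, 2), (1, 2)], 3)
        b = motif_from_edges([(2, 0), (2, 1), (0, 1)], 3)
        assert a.canonical_key == b.canonical_key

    def test_ffl_and_cycle_distinct(self):
        ffl = motif_from_edges([(0, 1), (0, 2), (1, 2)], 3)
        cyc = motif_from_edges([(0, 1), (1, 2), (2, 0)], 3)
        assert ffl.canonical_key != cyc.canonical_key

    def test_exhaustive_k3_against_permutation_orbit_oracle(self):
        """All 64 labeled 3-node digraphs: canonical keys collide exactly
        when the permutation orbits of the encodings coincide."""
        mats = []
        for code in range(64):
            bits = [(code >> t) & 1 for t in range(6)]
            e01, e10, e02, e20, e12, e21 = bits
            mats.append(((0, e01, e02), (e10, 0, e12), (e20, e21, 0)))

        def orbit(adj):
            out = set()
            for p in itertools.permutations(range(3)):
                out.add(tuple(tuple(adj[p[i]][p[j]] for j in range(3)) for i in range(3)))
            return frozenset(out)

        orbits = [orbit(m) for m in mats]
        keys = [canonical_form(m) for m in mats]
        for i in range(64):
            for j in range(i + 1, 64):
                assert (keys[i] == keys[j]) == (orbits[i] == orbits[j])

    def test_canonical_order_unique_normal_form(self):
        # a 3-cycle has 3 automorphisms; the chosen node tuple is the
        # lexicographic minimum over them
        adj = [[0, 1, 0], [0, 0, 1], [1, 0, 0]]
        key, tup = canonical_order(adj, ["b", "c", "a"])
        assert tup[0] == "a"


class TestEnumeration:
    def test_single_ffl(self, ffl_net):
        result = enumerate_connected_subgraphs(ffl_net, 3)
        assert len(result) == 1
        (inst_set,) = result.values()
        assert inst_set.motif.canonical_key == named_motif("FFL").canonical_key
        # canonical position order for the FFL is output, intermediate, input
        # (the minimal adjacency encoding puts the all-zero row first)
        assert inst_set.instances == {("Z", "Y", "X")}

    def test_single_cycle(self, cycle_net):
        result = enumerate_connected_subgraphs(cycle_net, 3)
        assert len(result) == 1
        (inst_set,) = result.values()
        assert inst_set.motif.canonical_key == named_motif("3-loop").canonical_key
        assert inst_set.count == 1

    def test_k_larger_than_network(self, ffl_net):
        assert enumerate_connected_subgraphs(ffl_net, 4) == {}

    @pytest.mark.parametrize("seed", range(6))
    def test_counts_match_brute_force_scan(self, seed):
        net = random_network(n=20, m=60, seed=seed)
        got = census_counts(net, 3)
        assert got == brute_force_triads(net)

    def test_dyad_census(self):
        net = DirectedNetwork.from_edges([("a", "b"), ("b", "a"), ("b", "c")])
        counts = census_counts(net, 2)
        assert counts[named_motif("mutual-dyad").canonical_key] == 1
        assert counts[named_motif("edge").canonical_key] == 1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_counts_match_igraph_triad_census(self, seed):
        """Independent cross-check: per-class counts agree with igraph's
        RAND-ESU census (exact at cut probability 0)."""
        igraph = pytest.importorskip("igraph")
        net = random_network(n=30, m=120, seed=seed)
        nodes = sorted(net.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        g = igraph.Graph(
            n=len(nodes),
            edges=[(idx[u], idx[v]) for u, v in net.edges],
            directed=True,
        )
        ig_counts = g.motifs_randesu(size=3)
        ours = census_counts(net, 3)
        for key, count in ours.items():
            adj = np.array(
                [
                    [(key[1] >> (9 - 1 - 3 * i - j)) & 1 for j in range(3)]
                    for i in range(3)
                ]
            )
            rep = igraph.Graph.Adjacency(adj.tolist(), mode="directed")
            cls = rep.isoclass()
            assert ig_counts[cls] == count
        # igraph reports NaN for disconnected classes; totals must agree
        total_ig = sum(c for c in ig_counts if c == c)
        assert total_ig == sum(ours.values())


class TestRandomization:
    def test_degrees_and_size_preserved(self):
        net = random_network(30, 120, seed=3)
        rand = degree_preserving_randomization(net, 42)
        assert rand.n_nodes == net.n_nodes
        assert rand.n_edges == net.n_edges
        assert Counter(u for u, _ in rand.edges) == Counter(u for u, _ in net.edges)
        assert Counter(v for _, v in rand.edges) == Counter(v for _, v in net.edges)
        assert not any(u == v for u, v in rand.edges)

    def test_self_loops_kept_in_place(self):
        net = DirectedNetwork.from_edges(
            [("a", "a"), ("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("b", "d")]
        )
        rand = degree_preserving_randomization(net, 0)
        assert ("a", "a") in rand.edges

    def test_fully_constrained_network_warns(self, ffl_net):
        with pytest.warns(UserWarning, match="no valid edge swaps"):
            degree_preserving_randomization(ffl_net, 0)


class TestSignificance:
    def test_planted_ffls_score_high(self):
        net, _ = generate_planted_network(
            n=40, m=80, plantings=[Planting(named_motif("FFL"), 12)], seed=5
        )
        scores = motif_significance(net, 3, n_random=30, seed=7)
        ffl = scores[named_motif("FFL").canonical_key]
        assert ffl.count >= 12
        assert ffl.z > 2.0

    def test_fully_constrained_network_degenerate(self, ffl_net):
        with pytest.warns(UserWarning):
            scores = motif_significance(ffl_net, 3, n_random=5, seed=0)
        ffl = scores[named_motif("FFL").canonical_key]
        assert ffl.degenerate and ffl.z == 0.0

    def test_determinism(self):
        net = random_network(25, 70, seed=9)
        a = motif_significance(net, 3, n_random=10, seed=4)
        b = motif_significance(net, 3, n_random=10, seed=4)
        assert {k: (v.count, v.z) for k, v in a.items()} == {
            k: (v.count, v.z) for k, v in b.items()
        }
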