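"""Combination/interaction counting and enumeration.

The closed-form counts are asserted directly; enumeration is checked
against brute-force subset generation and pairwise isomorphism.
"""

import itertools

import pytest

from hypermotifs.census import canonical_form, named_motif
from hypermotifs.combinatorics import (
    count_interaction_topologies,
    enumerate_combinations,
    enumerate_extensions,
    enumerate_interactions,
    max_linking_edges,
    max_shared_nodes,
)


class TestFormulas:
    @pytest.mark.parametrize("na,nb,expected", [(2, 2, 1), (3, 3, 2), (2, 3, 1)])
    def test_max_shared_nodes(self, na, nb, expected):
        assert max_shared_nodes(na, nb) == expected

    def test_max_shared_nodes_rejects_singletons(self):
        with pytest.raises(ValueError):
            max_shared_nodes(1, 3)

    @pytest.mark.parametrize("na,nb,directed,expected", [
        (3, 3, True, 18), (2, 2, False, 4), (2, 3, True, 12),
    ])
    def test_max_linking_edges(self, na, nb, directed, expected):
        assert max_linking_edges(na, nb, directed) == expected

    @pytest.mark.parametrize("na,nb,directed,expected", [
        (2, 2, False, 16), (2, 2, True, 256), (1, 1, True, 4),
    ])
    def test_interaction_topology_counts(self, na, nb, directed, expected):
        assert count_interaction_topologies(na, nb, directed) == expected

    def test_nonempty_flag_drops_zero_edge_case(self):
        assert count_interaction_topologies(1, 1, True, nonempty=True) == 3


class TestEnumerateCombinations:
    def test_two_ffls_give_twelve(self):
        ffl = named_motif("FFL")
        patterns = enumerate_combinations(ffl, ffl)
        assert len(patterns) == 12
        by_shared = {1: 0, 2: 0}
        for p in patterns:
            by_shared[p.n_shared] += 1
        assert by_shared == {1: 6, 2: 6}

    def test_two_mutual_dyads_give_one(self):
        dyad = named_motif("mutual-dyad")
        patterns = enumerate_combinations(dyad, dyad)
        assert len(patterns) == 1
        # the merged graph is a three-node chain of two mutual pairs
        assert patterns[0].merged.n_nodes == 3
        assert patterns[0].merged.n_edges == 4

    def test_dyad_ffl_gives_three(self):
        patterns = enumerate_combinations(named_motif("mutual-dyad"), named_motif("FFL"))
        notations = {p.notation for p in patterns}
        assert notations == {
            "mutual-dyad{partner}*FFL{input}",
            "mutual-dyad{partner}*FFL{intermediate}",
            "mutual-dyad{partner}*FFL{output}",
        }

    def test_merged_graphs_pairwise_non_isomorphic(self):
        patterns = enumerate_combinations(named_motif("FFL"), named_motif("FFL"))
        keys = [p.canonical_key for p in patterns]
        assert len(keys) == len(set(keys))

    def test_order_symmetry(self):
        a, b = named_motif("mutual-dyad"), named_motif("FFL")
        keys_ab = {p.canonical_key for p in enumerate_combinations(a, b)}
        keys_ba = {p.canonical_key for p in enumerate_combinations(b, a)}
        assert keys_ab == keys_ba

    def test_motifs_occur_induced_on_their_nodes(self):
        """Every emitted pattern realizes both motifs as induced subgraphs."""
        ffl = named_motif("FFL")
        for p in enumerate_combinations(ffl, ffl):
            a_nodes = [f"A{i}" for i in range(3)]
            ident = dict(zip(p.shared_b, p.shared_a))
            b_nodes = [f"A{ident[j]}" if j in ident else f"B{j}" for j in range(3)]
            for names in (a_nodes, b_nodes):
                induced = {
                    (u, v) for u, v in p.merged.edges if u in names and v in names
                }
                expect = {
                    (names[i], names[j])
                    for i in range(3)
                    for j in range(3)
                    if ffl.adjacency[i, j]
                }
                assert induced == expect

    def test_conflicting_identifications_are_excluded(self):
        ffl = named_motif("FFL")
        _, excluded = enumerate_combinations(ffl, ffl, with_exclusions=True)
        assert excluded == 9  # the misaligned two-node identifications

    def test_three_loops_can_share_an_edge(self):
        loop = named_motif("3-loop")
        patterns = enumerate_combinations(loop, loop)
        assert sorted(p.n_shared for p in patterns) == [1, 2]
        shared_edge = [p for p in patterns if p.n_shared == 2][0]
        assert shared_edge.merged.n_nodes == 4
        assert shared_edge.merged.n_edges == 5  # the shared edge counted once


class TestExtensions:
    def test_no_admissible_pairs_returns_core_only(self):
        # dyad*dyad: one exclusive node per motif -> 2 directed cross edges
        dyad = named_motif("mutual-dyad")
        (pattern,) = enumerate_combinations(dyad, dyad)
        extensions = enumerate_extensions(pattern)
        # brute force: subsets of the 2 admissible edges, deduplicated
        a_only = sorted(n for n in pattern.merged.nodes if n.startswith("A") and
                        n not in {f"A{i}" for i in pattern.shared_a})
        b_only = sorted(n for n in pattern.merged.nodes if n.startswith("B"))
        admissible = [(u, v) for u in a_only for v in b_only] + [
            (v, u) for u in a_only for v in b_only
        ]
        seen = set()
        for r in range(len(admissible) + 1):
            for subset in itertools.combinations(admissible, r):
                edges = set(pattern.merged.edges) | set(subset)
                nodes = sorted(pattern.merged.nodes)
                idx = {n: i for i, n in enumerate(nodes)}
                adj = [[0] * len(nodes) for _ in nodes]
                for u, v in edges:
                    adj[idx[u]][idx[v]] = 1
                seen.add(canonical_form(adj))
        assert len(extensions) == len(seen)

    def test_extensions_contain_core(self, ffl_cascade_pattern):
        for ext in enumerate_extensions(ffl_cascade_pattern):
            assert set(ffl_cascade_pattern.merged.edges) <= set(ext.edges)

    def test_extension_count_bounded_by_subset_count(self, ffl_cascade_pattern):
        # 2 exclusive nodes per side -> 4 cross pairs -> 8 directed edges
        exts = enumerate_extensions(ffl_cascade_pattern)
        assert 1 <= len(exts) <= 2**8


class TestInteractions:
    def test_dyad_pair_interactions_unique_and_linked(self):
        dyad = named_motif("mutual-dyad")
        patterns = enumerate_interactions(dyad, dyad)
        keys = [p.canonical_key for p in patterns]
        assert len(keys) == len(set(keys))
        assert all(len(p.links) >= 1 for p in patterns)
        # raw space is 2^8 subsets; unique topologies are far fewer
        assert 1 < len(patterns) < 255

    def test_max_links_guard(self):
        ffl = named_motif("FFL")
        with pytest.raises(ValueError, match="max_subsets"):
            enumerate_interactions(ffl, ffl, max_subsets=100)
        patterns = enumerate_interactions(ffl, ffl, max_links=1)
        assert all(len(p.links) == 1 for p in patterns)
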