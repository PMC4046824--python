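"""Identity-graph thresholding and Markov clustering."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pdzfam.cluster import (
    MCLDiagnostics,
    assign_families,
    build_identity_graph,
    mcl,
    read_abc_graph,
    write_abc_graph,
)


def identity_frame(ids, values):
    return pd.DataFrame(np.array(values, dtype=float), index=ids, columns=ids)


class TestBuildIdentityGraph:
    def test_all_below_cutoff_gives_edgeless_graph(self):
        table = identity_frame(
            list("abc"), [[100, 30, 30], [30, 100, 30], [30, 30, 100]]
        )
        g = build_identity_graph(table, cutoff=50)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 3

    def test_pair_at_exactly_cutoff_is_retained(self):
        # only pairs strictly below the cutoff are discarded
        table = identity_frame(list("ab"), [[100, 50.0], [50.0, 100]])
        g = build_identity_graph(table, cutoff=50)
        assert g.has_edge("a", "b") and g["a"]["b"]["weight"] == 50.0

    def test_edges_match_brute_force_threshold_scan(self):
        rng = np.random.default_rng(5)
        n = 5
        vals = np.full((n, n), 100.0)
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = rng.uniform(20, 90)
        ids = [f"n{i}" for i in range(n)]
        g = build_identity_graph(identity_frame(ids, vals), cutoff=50)
        for i in range(n):
            for j in range(i + 1, n):
                assert g.has_edge(ids[i], ids[j]) == (vals[i, j] >= 50)

    @pytest.mark.parametrize("cutoff", [0.0, -5.0, 101.0])
    def test_invalid_cutoff_rejected(self, cutoff):
        table = identity_frame(["a"], [[100.0]])
        with pytest.raises(ValueError, match="cutoff"):
            build_identity_graph(table, cutoff=cutoff)


def clique_graph(groups, weight=90.0, bridges=()):
    g = nx.Graph()
    for group in groups:
        g.add_nodes_from(group)
        for a, b in itertools.combinations(group, 2):
            g.add_edge(a, b, weight=weight)
    for a, b, w in bridges:
        g.add_edge(a, b, weight=w)
    return g


class TestMCL:
    def test_disjoint_cliques_become_separate_families(self):
        g = clique_graph([list("abc"), list("def")])
        result = mcl(g)
        assert sorted(sorted(f.members) for f in result.families) == [
            ["a", "b", "c"],
            ["d", "e", "f"],
        ]
        assert result.unclassified == frozenset()

    def test_isolated_node_is_unclassified(self):
        g = nx.Graph()
        g.add_node("solo")
        result = mcl(g)
        assert result.families == [] and result.unclassified == {"solo"}

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError, match="inflation"):
            mcl(nx.Graph(), inflation=1.0)

    def test_weak_bridge_split_matches_brute_force_best_two_partition(self):
        """Two dense groups joined by one weak edge: the MCL partition equals
        the 2-partition maximising total intra-cluster weight (equivalently,
        the minimum-weight cut)."""
        nodes = list("abcdefg")
        g = clique_graph(
            [list("abc"), list("defg")], weight=90.0, bridges=[("c", "d", 55.0)]
        )
        result = mcl(g, inflation=1.4)
        assert len(result.families) == 2
        got = sorted(sorted(f.members) for f in result.families)

        best_weight, best_partition = -1.0, None
        for mask in range(1, 2 ** (len(nodes) - 1)):
            side = {nodes[0]} | {
                nodes[i] for i in range(1, len(nodes)) if mask >> (i - 1) & 1
            }
            other = set(nodes) - side
            if not other:
                continue
            intra = sum(
                d["weight"]
                for a, b, d in g.edges(data=True)
                if (a in side) == (b in side)
            )
            if intra > best_weight:
                best_weight, best_partition = intra, (side, other)
        expected = sorted(sorted(s) for s in best_partition)
        assert got == expected

    def test_component_safety_and_partition_property(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            g = nx.Graph()
            nodes = [f"n{i}" for i in range(8)]
            g.add_nodes_from(nodes)
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.3:
                    g.add_edge(a, b, weight=float(rng.uniform(50, 100)))
            result = mcl(g)
            # partition property
            seen = [m for f in result.families for m in f.members] + list(
                result.unclassified
            )
            assert sorted(seen) == sorted(nodes)
            # component safety
            comp_of = {}
            for ci, comp in enumerate(nx.connected_components(g)):
                for v in comp:
                    comp_of[v] = ci
            for fam in result.families:
                assert len({comp_of[m] for m in fam.members}) == 1

    def test_columns_stay_stochastic_through_inflation(self):
        g = clique_graph([list("abcd"), list("efg")], bridges=[("d", "e", 60.0)])
        diag = MCLDiagnostics()
        mcl(g, diagnostics=diag)
        assert diag.iterations > 0
        assert diag.max_column_sum_error <= 1e-9

    def test_permutation_invariance(self):
        nodes = list("abcdefg")
        g = clique_graph(
            [list("abc"), list("defg")], weight=80.0, bridges=[("a", "g", 52.0)]
        )
        base = {frozenset(f.members) for f in mcl(g).families}
        relabel = {n: f"z{i}" for i, n in enumerate(reversed(nodes))}
        g2 = nx.relabel_nodes(g, relabel)
        permuted = {frozenset(f.members) for f in mcl(g2).families}
        assert permuted == {frozenset(relabel[m] for m in fam) for fam in base}

    def test_no_family_smaller_than_two(self):
        g = clique_graph([list("ab")], bridges=[])
        g.add_node("lonely")
        result = mcl(g)
        assert all(len(f.members) >= 2 for f in result.families)
        assert "lonely" in result.unclassified


class TestAssignFamilies:
    def test_empty_clustering_gives_empty_table(self):
        from pdzfam.cluster import ClusteringResult

        table = assign_families(ClusteringResult([], frozenset()))
        assert len(table) == 0

    def test_planted_families_recovered_exactly(self, planted_domains, planted_identity):
        _, families = planted_domains
        g = build_identity_graph(planted_identity, cutoff=50)
        result = mcl(g, inflation=1.4)
        got = {frozenset(f.members) for f in result.families}
        expected = {frozenset(members) for members in families.values()}
        assert got == expected
        assert result.unclassified == frozenset()

    def test_input_order_does_not_change_membership(self, planted_domains):
        from pdzfam.align import pairwise_identity_matrix

        domains, _ = planted_domains
        fwd = pairwise_identity_matrix(domains[:8])
        rev = pairwise_identity_matrix(domains[:8][::-1])
        fams_fwd = assign_families(mcl(build_identity_graph(fwd)))
        fams_rev = assign_families(mcl(build_identity_graph(rev)))
        assert fams_fwd.equals(fams_rev)


def test_abc_graph_round_trip(tmp_path):
    g = clique_graph([list("abc")], weight=72.5)
    path = tmp_path / "graph.abc"
    write_abc_graph(g, path)
    loaded = read_abc_graph(path)
    assert set(loaded.edges()) == set(g.edges())
    assert loaded["a"]["b"]["weight"] == 72.5
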