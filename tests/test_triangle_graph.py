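import math

import numpy as np
import pytest

from grnbalance.balance_analysis import enumerate_triangles
from grnbalance.triangle_graph import (
    build_triangle_graph,
    energy_assortativity,
    giant_component_stats,
    mixing_matrix,
)
from conftest import (
    brute_triangle_adjacency,
    net_from_edges,
    random_signed_network,
)


def complete_net(n, weight=1.0):
    return net_from_edges(n, {(i, j): weight for i in range(n) for j in range(i + 1, n)})


class TestBuildTriangleGraph:
    def test_shared_edge_single_adjacency(self):
        net = net_from_edges(
            4, {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0, (1, 3): 1.0, (2, 3): -1.0}
        )
        tg = build_triangle_graph(enumerate_triangles(net))
        assert tg.n_nodes == 2 and tg.adjacency == {(0, 1)}

    def test_disjoint_triples_no_adjacency(self):
        edges = {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0,
                 (3, 4): 1.0, (4, 5): -1.0, (3, 5): 1.0}
        tg = build_triangle_graph(enumerate_triangles(net_from_edges(6, edges)))
        assert tg.n_nodes == 2 and tg.adjacency == set()

    def test_k5_matches_brute_force(self):
        net = complete_net(5)
        tris = enumerate_triangles(net)
        tg = build_triangle_graph(tris)
        triples = [tuple(net.gene_ids.index(g) for g in t.genes) for t in tris]
        assert tg.adjacency == brute_triangle_adjacency(triples)
        # in K5 every triangle pair sharing 2 vertices: degree 3*(5-3) = 6
        degree = {i: 0 for i in range(tg.n_nodes)}
        for a, b in tg.adjacency:
            degree[a] += 1
            degree[b] += 1
        assert set(degree.values()) == {6}

    def test_random_networks_match_brute_force(self, rng):
        for _ in range(10):
            net = random_signed_network(12, 0.4, rng)
            tris = enumerate_triangles(net)
            tg = build_triangle_graph(tris)
            triples = [tuple(net.gene_ids.index(g) for g in t.genes) for t in tris]
            assert tg.adjacency == brute_triangle_adjacency(triples)


class TestMixingMatrix:
    def test_single_pair_symmetric_increment(self):
        net = net_from_edges(
            4, {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0, (1, 3): 1.0, (2, 3): -1.0}
        )
        tg = build_triangle_graph(enumerate_triangles(net))
        mm = mixing_matrix(tg, n_bins=4)
        assert mm.counts.sum() == 2.0
        np.testing.assert_array_equal(mm.counts, mm.counts.T)

    def test_no_adjacency_zero_matrix(self):
        edges = {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0}
        tg = build_triangle_graph(enumerate_triangles(net_from_edges(3, edges)))
        assert mixing_matrix(tg).counts.sum() == 0.0

    def test_matches_brute_force_double_loop(self, rng):
        net = random_signed_network(12, 0.45, rng)
        tg = build_triangle_graph(enumerate_triangles(net))
        mm = mixing_matrix(tg, n_bins=8)
        nb = len(mm.bin_edges) - 1
        oracle = np.zeros((nb, nb))
        e = [t.energy for t in tg.triangles]

        def bin_of(x):
            for b in range(nb):
                if mm.bin_edges[b] <= x <= mm.bin_edges[b + 1]:
                    if x < mm.bin_edges[b + 1] or b == nb - 1:
                        return b
            raise AssertionError

        for i, j in tg.adjacency:
            oracle[bin_of(e[i]), bin_of(e[j])] += 1
            oracle[bin_of(e[j]), bin_of(e[i])] += 1
        np.testing.assert_array_equal(mm.counts, oracle)

    def test_total_is_twice_adjacency_count(self, rng):
        net = random_signed_network(11, 0.5, rng)
        tg = build_triangle_graph(enumerate_triangles(net))
        mm = mixing_matrix(tg)
        assert mm.counts.sum() == 2 * tg.n_adjacencies

    def test_row_sums_are_degree_weighted_bin_counts(self, rng):
        net = random_signed_network(12, 0.5, rng)
        tg = build_triangle_graph(enumerate_triangles(net))
        mm = mixing_matrix(tg, n_bins=6)
        nb = len(mm.bin_edges) - 1
        e = np.array([t.energy for t in tg.triangles])
        bins = np.clip(np.digitize(e, mm.bin_edges) - 1, 0, nb - 1)
        degree = np.zeros(tg.n_nodes)
        for a, b in tg.adjacency:
            degree[a] += 1
            degree[b] += 1
        expected = np.array(
            [degree[bins == k].sum() for k in range(nb)]
        )
        np.testing.assert_array_equal(mm.counts.sum(axis=1), expected)

    def test_normalization(self, rng):
        net = random_signed_network(10, 0.5, rng)
        tg = build_triangle_graph(enumerate_triangles(net))
        raw = mixing_matrix(tg, n_bins=5)
        norm = mixing_matrix(tg, n_bins=5, normalize_by=tg.n_nodes)
        np.testing.assert_allclose(norm.counts, raw.counts / tg.n_nodes)


class TestGiantComponentStats:
    def test_single_component_fraction(self):
        net = net_from_edges(
            4, {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0, (1, 3): -1.0, (2, 3): 1.0}
        )
        tg = build_triangle_graph(enumerate_triangles(net))
        stats = giant_component_stats(tg)
        assert stats.giant_size == tg.n_nodes
        assert stats.frac_imbalanced_in_giant == 1.0

    def test_isolated_frustrated_not_in_giant(self):
        # two balanced triangles sharing an edge (the giant), one isolated
        # frustrated triple
        edges = {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0, (1, 3): 1.0, (2, 3): 1.0,
                 (4, 5): -1.0, (5, 6): 1.0, (4, 6): 1.0}
        tg = build_triangle_graph(enumerate_triangles(net_from_edges(7, edges)))
        stats = giant_component_stats(tg)
        assert stats.giant_size == 2
        assert stats.n_imbalanced == 1
        assert stats.frac_imbalanced_in_giant == 0.0
        assert stats.frac_imbalanced_outside == 1.0

    def test_empty_graph_degenerate(self):
        tg = build_triangle_graph([])
        stats = giant_component_stats(tg)
        assert stats.giant_size == 0 and stats.n_imbalanced == 0
        assert math.isnan(stats.frac_imbalanced_in_giant)

    def test_fraction_identity(self, rng):
        # balanced-in-giant + imbalanced-in-giant = giant size
        net = random_signed_network(12, 0.4, rng)
        tg = build_triangle_graph(enumerate_triangles(net))
        stats = giant_component_stats(tg)
        giant_members = [
            i for i, lbl in enumerate(stats.labels) if lbl == 0
        ]
        balanced_in_giant = sum(
            1 for i in giant_members if tg.triangles[i].balance_class == "balanced"
        )
        assert balanced_in_giant + stats.n_imbalanced_in_giant == stats.giant_size


class TestEnergyAssortativity:
    def test_equal_energies_undefined(self):
        net = complete_net(4)  # all triangle energies -1
        tg = build_triangle_graph(enumerate_triangles(net))
        assert math.isnan(energy_assortativity(tg))

    def test_perfect_assortativity(self):
        # two disjoint adjacent pairs with energies (e, e) and (-e, -e)
        edges = {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0, (1, 3): 1.0, (2, 3): 1.0,
                 (4, 5): -1.0, (5, 6): 1.0, (4, 6): 1.0, (5, 7): 1.0, (6, 7): -1.0}
        tg = build_triangle_graph(enumerate_triangles(net_from_edges(8, edges)))
        assert tg.n_adjacencies == 2
        energies = sorted(t.energy for t in tg.triangles)
        assert energies == [-1.0, -1.0, 1.0, 1.0]
        assert energy_assortativity(tg) == pytest.approx(1.0)

    def test_no_adjacency_undefined(self):
        edges = {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0}
        tg = build_triangle_graph(enumerate_triangles(net_from_edges(3, edges)))
        assert math.isnan(energy_assortativity(tg))

    def test_matches_direct_edge_list_correlation(self, rng):
        net = random_signed_network(13, 0.4, rng)
        tg = build_triangle_graph(enumerate_triangles(net))
        if tg.n_adjacencies < 2:
            pytest.skip("degenerate draw")
        e = [t.energy for t in tg.triangles]
        xs, ys = [], []
        for i, j in tg.adjacency:
            xs += [e[i], e[j]]
            ys += [e[j], e[i]]
        mx, my = np.mean(xs), np.mean(ys)
        num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        den = math.sqrt(
            sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys)
        )
        assert energy_assortativity(tg) == pytest.approx(num / den, rel=1e-10)
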