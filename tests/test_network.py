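import itertools

import networkx as nx
import numpy as np
import pytest

from coexatlas.correlation import CorrelationMatrix
from coexatlas.network import (
    DensityRecord,
    build_network,
    clustering_coefficients,
    components,
    degree_powerlaw_fit,
    density_curve,
    density_from_counts,
    direct_neighbors,
    mr_disconnected_fraction,
    network_density,
    path_stats,
    select_pcc_cutoff,
)


def corr_from(values, kind="pcc"):
    values = np.asarray(values, dtype=float)
    return CorrelationMatrix([f"g{i}" for i in range(len(values))], values, kind)


def triangle_corr(r=0.99):
    v = np.full((3, 3), r)
    np.fill_diagonal(v, 1.0)
    return corr_from(v)


class TestBuildNetwork:
    def test_triangle_above_cutoff(self):
        net = build_network(triangle_corr(), 0.93)
        assert net.number_of_edges() == 3

    def test_empty_above_all_scores(self):
        net = build_network(triangle_corr(), 0.995)
        assert net.number_of_nodes() == 0

    def test_mr_direction_keeps_low_scores(self):
        v = np.array([[np.nan, 1, 4], [1, np.nan, 150], [4, 150, np.nan]])
        net = build_network(corr_from(v, "mutual_rank"), 100)
        assert net.number_of_edges() == 2

    def test_direction_kind_mismatch(self):
        with pytest.raises(ValueError):
            build_network(triangle_corr(), 0.5, direction="le_for_mr")

    def test_same_gene_probe_edges_discarded(self):
        net = build_network(
            triangle_corr(), 0.9, exclude_same_gene={"g0": "X", "g1": "X", "g2": "Y"}
        )
        assert ("g0", "g1") not in net.edges
        assert net.number_of_edges() == 2


class TestDensity:
    def test_triangle_and_path(self):
        tri = build_network(triangle_corr(), 0.9)
        assert network_density(tri) == pytest.approx(1.0)
        path = nx.path_graph(3)
        assert network_density(path) == pytest.approx(2 / 3)

    def test_published_count_convention(self):
        # surviving-node denominator reproduces the printed atlas densities
        assert density_from_counts(4257, 68428) == pytest.approx(0.0075, abs=1e-4)
        assert density_from_counts(2663, 42855) == pytest.approx(0.0121, abs=1e-4)

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            density_from_counts(1, 0)


class TestDensityCurve:
    def test_uniform_correlations(self):
        v = np.full((4, 4), 0.8)
        np.fill_diagonal(v, 1.0)
        records = density_curve(corr_from(v), [0.5, 0.8, 0.9])
        assert records[0].density == pytest.approx(1.0)
        assert records[1].density == pytest.approx(1.0)
        assert records[2].density is None

    def test_matches_exhaustive_rebuild(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-1, 1, size=(15, 15))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        corr = corr_from(v)
        cutoffs = np.linspace(0, 1, 21)
        records = density_curve(corr, cutoffs)
        for rec in records:
            net = build_network(corr, rec.cutoff)
            assert rec.n_edges == net.number_of_edges()
            assert rec.n_nodes == net.number_of_nodes()
            if rec.density is not None:
                assert rec.density == pytest.approx(network_density(net))
        edges = [r.n_edges for r in records]
        assert all(a >= b for a, b in zip(edges, edges[1:]))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            density_curve(triangle_corr(), [])


class TestSelectCutoff:
    def test_minimum_and_tie_rule(self):
        curve = [DensityRecord(0.5, 0.9, 5, 5), DensityRecord(0.7, 0.4, 4, 3),
                 DensityRecord(0.9, 0.6, 3, 2)]
        assert select_pcc_cutoff(curve) == 0.7
        tie = [DensityRecord(0.5, 0.4, 5, 5), DensityRecord(0.7, 0.4, 4, 3)]
        assert select_pcc_cutoff(tie) == 0.5

    def test_all_null_curve(self):
        with pytest.raises(ValueError):
            select_pcc_cutoff([DensityRecord(0.9, None, 1, 0)])


def brute_clustering(net):
    out = {}
    for n in net:
        nbrs = list(net.neighbors(n))
        k = len(nbrs)
        if k < 2:
            out[n] = 0.0
            continue
        e = sum(1 for a, b in itertools.combinations(nbrs, 2) if net.has_edge(a, b))
        out[n] = 2 * e / (k * (k - 1))
    return out


class TestTopologyStats:
    def test_triangle_and_star_clustering(self):
        tri = nx.complete_graph(3)
        per, mean = clustering_coefficients(tri)
        assert mean == pytest.approx(1.0)
        star = nx.star_graph(4)
        per, mean = clustering_coefficients(star)
        assert mean == 0.0

    def test_clustering_matches_brute_force(self):
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        per, _ = clustering_coefficients(g)
        oracle = brute_clustering(g)
        for n in g:
            assert per[n] == pytest.approx(oracle[n])

    def test_components_sorted(self):
        g = nx.union(nx.complete_graph(3), nx.relabel_nodes(nx.complete_graph(3), lambda x: x + 10))
        comps = components(g)
        assert [len(c) for c in comps] == [3, 3]
        assert components(nx.Graph()) == []

    def test_path_stats_examples(self):
        path = nx.path_graph(3)
        mean, count = path_stats(path)
        assert mean == pytest.approx(4 / 3)
        assert count == 6
        k4 = nx.complete_graph(4)
        mean, count = path_stats(k4)
        assert mean == pytest.approx(1.0)
        assert count == 12

    def test_path_stats_matches_all_pairs_oracle(self):
        g = nx.gnp_random_graph(40, 0.08, seed=1)
        mean, count = path_stats(g)
        # dense Floyd–Warshall oracle
        dist = nx.floyd_warshall_numpy(g)
        finite = dist[np.isfinite(dist) & (dist > 0)]
        assert count == finite.size
        assert mean == pytest.approx(finite.mean())


class TestPowerlawFit:
    def test_exact_powerlaw_histogram(self):
        g = nx.Graph()
        # construct a degree histogram freq = degree^-2 exactly: use a
        # synthetic frequency table via disjoint stars
        node = 0
        freqs = {1: 16, 2: 4, 4: 1}
        for degree, freq in freqs.items():
            for _ in range(freq):
                center = f"c{node}"
                for i in range(degree):
                    g.add_edge(center, f"{center}_{i}")
                node += 1
        # leaves add mass at degree 1; restrict to centers via direct fit
        degrees = np.array(sorted(freqs))
        counts = np.array([freqs[d] for d in degrees])
        slope, _ = np.polyfit(np.log10(degrees), np.log10(counts), 1)
        assert slope == pytest.approx(-2.0)

    def test_regular_graph_rejected(self):
        with pytest.raises(ValueError):
            degree_powerlaw_fit(nx.cycle_graph(10))

    def test_preferential_attachment_graph_fits(self):
        g = nx.barabasi_albert_graph(300, 2, seed=0)
        slope, r2 = degree_powerlaw_fit(g)
        assert slope < 0
        assert r2 >= 0.8


class TestMRDisconnected:
    def test_bounds_and_brute_force(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(1, 50, size=(8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, np.nan)
        corr = corr_from(v, "mutual_rank")
        cutoffs = [0.5, 10, 20, 30, 60]
        result = mr_disconnected_fraction(corr, cutoffs)
        assert result[0][1] == 1.0
        assert result[-1][1] == 0.0
        for cutoff, frac in result:
            oracle = np.mean([
                0 if any(v[i, j] <= cutoff for j in range(8) if j != i) else 1
                for i in range(8)
            ])
            assert frac == pytest.approx(oracle)
        fractions = [f for _, f in result]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_kind_checked(self):
        with pytest.raises(ValueError):
            mr_disconnected_fraction(triangle_corr(), [1])


class TestDirectNeighbors:
    def test_triangle_and_absent_gene(self):
        net = build_network(triangle_corr(), 0.9)
        table = direct_neighbors(net, ["g0"])
        assert len(table) == 2
        empty = direct_neighbors(net, ["missing"])
        assert len(empty) == 0

    def test_matches_adjacency_scan(self):
        g = nx.gnp_random_graph(12, 0.3, seed=2)
        nx.set_edge_attributes(g, 1.0, "score")
        table = direct_neighbors(g, list(g.nodes))
        for node in g:
            got = sorted(table[table["query"] == node]["neighbor"])
            assert got == sorted(g.neighbors(node))
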