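import math

import numpy as np
import pytest
from scipy import stats

from zonebreak.network import (
    DegreeDistribution,
    Network,
    UndefinedKappaError,
    cluster_sizes,
    generate_er,
    kappa,
    largest_cluster_fraction,
    read_edge_list,
    write_edge_list,
)

from conftest import network_from_edges, random_small_network


class TestGenerateER:
    def test_zero_mean_degree_gives_isolated_nodes(self):
        net = generate_er(10, 0.0, seed=1)
        assert net.n_edges == 0
        assert net.n_alive == 10

    def test_full_mean_degree_gives_complete_graph(self):
        net = generate_er(5, 4.0, seed=7)
        assert net.n_edges == 10
        assert all(d == 4 for d in net.degrees)

    @pytest.mark.parametrize("n, k", [(10, 10), (10, -0.5), (1, 0)])
    def test_invalid_parameters_rejected(self, n, k):
        with pytest.raises(ValueError):
            generate_er(n, k, seed=0)

    def test_same_seed_reproduces_graph(self):
        a = generate_er(300, 6.0, seed=42)
        b = generate_er(300, 6.0, seed=42)
        assert a.edges() == b.edges()

    def test_empirical_mean_degree_near_target(self):
        # N=200, <k>=4: sd of the empirical mean degree is
        # 2*sqrt(M p (1-p))/N with M = C(200,2) pairs
        n, k = 200, 4.0
        p = k / (n - 1)
        m = n * (n - 1) / 2
        se = 2.0 * math.sqrt(m * p * (1 - p)) / n
        net = generate_er(n, k, seed=3)
        mean_deg = 2 * net.n_edges / n
        assert abs(mean_deg - k) < 3 * se

    def test_degree_distribution_is_poisson(self):
        # pooled degrees over 10 seeds of ER(10000, 20) vs Poisson(20)
        degs = []
        for seed in range(10):
            degs.append(generate_er(10_000, 20.0, seed=seed).alive_degrees())
        degs = np.concatenate(degs)
        kmax = degs.max()
        observed = np.bincount(degs, minlength=kmax + 1)
        expected = stats.poisson.pmf(np.arange(kmax + 1), 20.0) * degs.size
        # merge sparse tails so every expected bin has mass >= 5
        lo = np.searchsorted(np.cumsum(expected), 5.0) + 1
        hi = kmax - np.searchsorted(np.cumsum(expected[::-1]), 5.0) - 1
        obs = np.concatenate(
            [[observed[:lo].sum()], observed[lo:hi], [observed[hi:].sum()]]
        )
        exp = np.concatenate(
            [[expected[:lo].sum()], expected[lo:hi], [expected[hi:].sum()]]
        )
        exp *= obs.sum() / exp.sum()
        _, pvalue = stats.chisquare(obs, exp)
        assert pvalue > 0.001


class TestKappa:
    def test_triangle_is_exactly_critical(self, triangle):
        assert kappa(triangle) == pytest.approx(2.0)

    def test_star_is_exactly_critical(self, star_k13):
        # degrees (3,1,1,1): <k2>=3, <k>=1.5
        assert kappa(star_k13) == pytest.approx(2.0)

    def test_fresh_er_kappa_is_mean_degree_plus_one(self):
        # Poisson identity <k2> = <k>^2 + <k> implies kappa = <k> + 1
        vals = [kappa(generate_er(5000, 12.0, seed=s)) for s in range(10)]
        assert np.mean(vals) == pytest.approx(13.0, abs=0.15)

    def test_all_degrees_zero_is_undefined(self):
        net = Network(n_nodes=3, adjacency=[[], [], []])
        with pytest.raises(UndefinedKappaError):
            kappa(net)

    def test_matches_bruteforce_moments_after_removals(self):
        # oracle: recompute both moments from scratch on the alive subgraph
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 200:
            net = random_small_network(rng)
            for v in rng.permutation(net.n_nodes)[: int(net.n_nodes * rng.random())]:
                net.remove_node(int(v))
            degs = []
            for v in range(net.n_nodes):
                if net.alive[v]:
                    degs.append(
                        sum(1 for u in net.adjacency[v] if net.alive[u])
                    )
            if not degs or sum(degs) == 0:
                continue
            oracle = sum(d * d for d in degs) / sum(degs)
            assert kappa(net) == pytest.approx(oracle, abs=1e-12)
            checked += 1


class TestClusters:
    def test_two_disjoint_triangles(self):
        net = network_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert cluster_sizes(net) == [3, 3]
        assert largest_cluster_fraction(net) == 0.5

    def test_isolated_nodes(self):
        net = Network(n_nodes=4, adjacency=[[], [], [], []])
        assert cluster_sizes(net) == [1, 1, 1, 1]
        assert largest_cluster_fraction(net) == 0.25

    def test_path_with_middle_removed(self, path5):
        path5.remove_node(2)
        assert cluster_sizes(path5) == [2, 2]

    def test_connected_graph_fraction_is_one(self, triangle):
        assert largest_cluster_fraction(triangle) == 1.0

    def test_empty_graph(self):
        net = Network(n_nodes=2, adjacency=[[1], [0]])
        net.remove_node(0)
        net.remove_node(1)
        assert cluster_sizes(net) == []
        with pytest.raises(ValueError):
            largest_cluster_fraction(net)

    def test_sizes_sum_to_alive_count_after_random_removals(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            net = random_small_network(rng)
            n_remove = int(rng.integers(0, net.n_nodes))
            for v in rng.permutation(net.n_nodes)[:n_remove]:
                net.remove_node(int(v))
            assert sum(cluster_sizes(net)) == net.n_alive


class TestEdgeListIO:
    def test_small_file_roundtrip(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("0 1\n1 2\n")
        net = read_edge_list(path)
        assert net.n_nodes == 3
        assert net.edges() == [(0, 1), (1, 2)]

    def test_er_graph_roundtrip_is_identity(self, tmp_path):
        net = generate_er(150, 3.0, seed=9)
        path = tmp_path / "er.txt"
        write_edge_list(net, path)
        back = read_edge_list(path)
        assert back.n_nodes == net.n_nodes
        assert back.edges() == net.edges()

    def test_self_loop_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 1\n2 2\n")
        with pytest.raises(ValueError, match="self-loop"):
            read_edge_list(path)

    def test_duplicate_edge_strict_vs_dedupe(self, tmp_path):
        path = tmp_path / "dup.txt"
        path.write_text("0 1\n1 0\n1 2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_edge_list(path)
        net = read_edge_list(path, dedupe=True)
        assert net.edges() == [(0, 1), (1, 2)]

    @pytest.mark.parametrize("content", ["0 x\n", "-1 2\n", "0 1 2\n"])
    def test_malformed_lines_rejected(self, content, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(content)
        with pytest.raises(ValueError):
            read_edge_list(path)


class TestDegreeDistribution:
    def test_rejects_unnormalised(self):
        with pytest.raises(ValueError):
            DegreeDistribution(probabilities={0: 0.5, 1: 0.4}, mean=0.4)

    def test_rejects_inconsistent_mean(self):
        with pytest.raises(ValueError):
            DegreeDistribution(probabilities={0: 0.5, 2: 0.5}, mean=0.9)

    def test_poisson_is_normalised_with_consistent_mean(self):
        dist = DegreeDistribution.poisson(20.0)
        assert math.fsum(dist.probabilities.values()) == pytest.approx(1.0, abs=1e-12)
        assert dist.mean == pytest.approx(20.0, abs=1e-9)

    def test_empirical_from_degrees(self):
        dist = DegreeDistribution.from_degrees([2, 2, 2, 0])
        assert dist.probabilities == {0: 0.25, 2: 0.75}
        assert dist.mean == pytest.approx(1.5)
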