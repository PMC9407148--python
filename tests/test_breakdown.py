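import numpy as np
import pandas as pd
import pytest

from zonebreak.breakdown import (
    NonTerminationError,
    RemovalConfig,
    run_breakdown,
    run_ensemble,
)
from zonebreak.network import generate_er, kappa, largest_cluster_fraction
from zonebreak.zoning import zone_by_kshell, zone_by_sorted_degree

from conftest import network_from_edges


class TestRemovalConfig:
    def test_r_equal_one_rejected(self):
        with pytest.raises(ValueError, match="terminate"):
            RemovalConfig(r=1.0, seed=0)

    @pytest.mark.parametrize("r", [-0.1, 1.5])
    def test_r_out_of_range_rejected(self, r):
        with pytest.raises(ValueError):
            RemovalConfig(r=r, seed=0)

    def test_invalid_f_stop_rejected(self):
        with pytest.raises(ValueError):
            RemovalConfig(r=0.0, seed=0, f_stop=1.0)


class TestRunBreakdown:
    def test_single_edge_graph_is_already_broken(self):
        # two nodes, one edge: kappa = 1 <= 2 from the start
        net = network_from_edges(2, [(0, 1)])
        zones = zone_by_sorted_degree(net)
        result = run_breakdown(net, zones, RemovalConfig(r=0.0, seed=1))
        assert result.terminated
        assert result.n_removed == 0
        assert result.final_cluster_sizes == (2,)

    def test_same_seed_reproduces_removal_order(self):
        order = []
        for _ in range(2):
            net = generate_er(500, 10.0, seed=4)
            zones = zone_by_kshell(net)
            res = run_breakdown(net, zones, RemovalConfig(r=0.4, seed=17))
            order.append(res.removal_order)
        assert order[0] == order[1]

    def test_conservation_and_first_crossing(self):
        net = generate_er(800, 12.0, seed=6)
        zones = zone_by_sorted_degree(net)
        res = run_breakdown(
            net, zones, RemovalConfig(r=0.3, seed=2, record_trajectory=True)
        )
        assert res.terminated
        assert sum(res.final_cluster_sizes) == res.n_nodes - res.n_removed
        # kappa crosses the threshold exactly at the stopping removal
        kappas = res.trajectory.kappa
        assert kappas[res.n_removed - 1] <= 2.0 or np.isnan(kappas[res.n_removed - 1])
        assert kappas[res.n_removed - 2] > 2.0

    def test_trajectory_f_increases_by_one_over_n(self):
        net = generate_er(400, 8.0, seed=8)
        zones = zone_by_sorted_degree(net)
        res = run_breakdown(
            net, zones, RemovalConfig(r=0.0, seed=3, record_trajectory=True)
        )
        steps = np.diff(res.trajectory.f)
        assert np.allclose(steps, 1.0 / 400)

    def test_trajectory_matches_final_network_state(self):
        net = generate_er(400, 8.0, seed=12)
        zones = zone_by_kshell(net)
        res = run_breakdown(
            net, zones, RemovalConfig(r=0.2, seed=5, record_trajectory=True)
        )
        # the network was mutated in place; its final S must equal the
        # last trajectory sample, and the crossing state must match the
        # recorded cluster sizes
        assert res.trajectory.S[-1] == pytest.approx(largest_cluster_fraction(net))
        assert res.final_cluster_sizes[0] == max(res.final_cluster_sizes)

    def test_incremental_kappa_equals_recomputation(self):
        # replay the removal order on a fresh copy and recompute kappa
        # from scratch at 100 random checkpoints
        net = generate_er(600, 10.0, seed=14)
        replay = net.copy()
        zones = zone_by_sorted_degree(net)
        res = run_breakdown(
            net, zones, RemovalConfig(r=0.3, seed=7, record_trajectory=True)
        )
        rng = np.random.default_rng(0)
        checkpoints = set(
            int(i) for i in rng.integers(0, len(res.removal_order), size=100)
        )
        for t, v in enumerate(res.removal_order):
            replay.remove_node(v)
            if t in checkpoints:
                assert res.trajectory.kappa[t] == pytest.approx(
                    kappa(replay), abs=1e-9
                )

    def test_f_stop_continues_past_breakdown(self):
        net = generate_er(1000, 15.0, seed=20)
        zones = zone_by_sorted_degree(net)
        res = run_breakdown(
            net,
            zones,
            RemovalConfig(r=0.0, seed=9, record_trajectory=True, f_stop=0.97),
        )
        assert len(res.removal_order) >= round(0.97 * 1000)
        assert res.n_removed <= len(res.removal_order)
        assert not np.isnan(res.trajectory.s_at(0.97, 1000))

    def test_attempt_guard_raises(self):
        net = generate_er(500, 10.0, seed=21)
        zones = zone_by_sorted_degree(net)
        with pytest.raises(NonTerminationError):
            run_breakdown(net, zones, RemovalConfig(r=0.9, seed=1, max_attempts=10))

    def test_breakdown_fraction_near_analytic_identity(self):
        # uniform removal from ER: kappa = <k>(1-f) + 1, so f_c = 1 - 1/<k>
        fcs = []
        for rep in range(8):
            net = generate_er(3000, 20.0, seed=30 + rep)
            zones = zone_by_sorted_degree(net)
            fcs.append(run_breakdown(net, zones, RemovalConfig(r=0.0, seed=rep)).f_c)
        assert np.mean(fcs) == pytest.approx(1 - 1 / 20, abs=0.015)


class TestRunEnsemble:
    def test_identical_master_seed_gives_identical_summaries(self):
        kwargs = dict(record_trajectory=True, f_stop=0.9)
        a = run_ensemble(300, 8.0, "k_shell", [0.0, 0.5], 3, 123, **kwargs)
        b = run_ensemble(300, 8.0, "k_shell", [0.0, 0.5], 3, 123, **kwargs)
        pd.testing.assert_frame_equal(a.runs, b.runs)
        pd.testing.assert_frame_equal(a.curves, b.curves)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            run_ensemble(300, 8.0, "nearest_neighbor", [0.0], 2, 1)
        with pytest.raises(ValueError):
            run_ensemble(300, 8.0, "k_shell", [0.0], 0, 1)

    def test_normalised_cluster_count_is_one_at_r_zero(self):
        summary = run_ensemble(300, 8.0, "k_sorted", [0.0, 0.4], 3, 7)
        per_r = summary.per_r.set_index("r")
        assert per_r.loc[0.0, "n_clusters_norm"] == pytest.approx(1.0)

    def test_random_zoning_breakdown_is_r_invariant(self):
        # structure-blind zones make the removal order exchangeable with
        # uniform removal, so f_c must not depend on r
        a = run_ensemble(2000, 15.0, "random", [0.0], 12, 55)
        b = run_ensemble(2000, 15.0, "random", [0.8], 12, 56)
        ma, sa = a.per_r.f_c_mean[0], a.per_r.f_c_sem[0]
        mb, sb = b.per_r.f_c_mean[0], b.per_r.f_c_sem[0]
        assert abs(ma - mb) < 3 * np.hypot(sa, sb)

    def test_runs_table_schema(self):
        summary = run_ensemble(300, 8.0, "k_sorted", [0.2], 2, 3)
        expected = {
            "replicate",
            "r",
            "model",
            "n_removed",
            "f_c",
            "n_clusters",
            "largest_cluster",
            "kappa_final",
            "inner_fraction",
            "seed",
            "n_nodes",
            "mean_degree",
        }
        assert expected <= set(summary.runs.columns)
        assert len(summary.runs) == 2
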