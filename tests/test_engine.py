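"""Filtering schedule, calibration, network scoring, and the outer loop."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amend.engine import (
    DEFAULT_DECAY_GRID,
    AmendConfig,
    PSOSettings,
    calibrate_decay,
    filtering_rate,
    iterate_once,
    optimize_eta0,
    run_amend,
    score_network,
    simulate_sizes,
)
from amend.evaluation import jaccard
from amend.network import InteractionNetwork
from amend.synthetic import SyntheticSpec, generate_instance


class TestFilteringRate:
    def test_first_iteration_is_eta0(self):
        assert filtering_rate(1, 0.5, 3.7) == 0.5

    def test_no_decay_constant(self):
        assert filtering_rate(3, 0.5, 0.0) == 0.5

    def test_worked_value(self):
        assert filtering_rate(2, 0.5, 0.1) == pytest.approx(0.45242, abs=1e-5)

    @pytest.mark.parametrize("i,eta0,d", [(0, 0.5, 1), (1, 0.0, 1), (1, 1.0, 1), (1, 0.5, -1)])
    def test_domain_violations(self, i, eta0, d):
        with pytest.raises(ValueError):
            filtering_rate(i, eta0, d)


class TestSimulateSizes:
    def test_ceil_halving_terminates_at_one(self):
        assert simulate_sizes(100, 0.5, 0.0) == [100, 50, 25, 13, 7, 4, 2, 1]

    def test_large_decay_single_effective_step(self):
        sizes = simulate_sizes(100, 0.5, 50.0)
        assert sizes[1] == math.ceil(100 * 0.5)
        assert sizes[-1] == sizes[1]  # rates collapse to ~0 after one step

    @settings(max_examples=500, deadline=None)
    @given(
        st.integers(2, 5000),
        st.floats(0.05, 0.95),
        st.floats(0, 8),
        st.floats(0.001, 2),
    )
    def test_final_size_monotone_in_decay(self, n0, eta0, d, delta):
        lo = simulate_sizes(n0, eta0, d)[-1]
        hi = simulate_sizes(n0, eta0, d + delta)[-1]
        assert hi >= lo


class TestCalibrateDecay:
    def test_target_one_returns_smallest_grid_value(self):
        assert calibrate_decay(100, 0.5, 1) == min(DEFAULT_DECAY_GRID)

    def test_smallest_admissible_grid_value(self):
        d = calibrate_decay(1000, 0.5, 15)
        grid = sorted(DEFAULT_DECAY_GRID)
        assert simulate_sizes(1000, 0.5, d)[-1] >= 15
        prev = [g for g in grid if g < d]
        assert prev and simulate_sizes(1000, 0.5, prev[-1])[-1] < 15

    def test_unreachable_target_errors(self):
        with pytest.raises(ValueError):
            calibrate_decay(1000, 0.9, 1000)

    def test_domain(self):
        with pytest.raises(ValueError):
            calibrate_decay(10, 0.5, 11)


class TestScoreNetwork:
    def test_product_of_means(self, triangle):
        z = pd.Series({"a": 2.0, "b": 2.0, "c": 2.0})
        # clique members all have core-clustering coefficient 1
        assert score_network(triangle, z) == pytest.approx(2.0)

    def test_zero_mean_z_zero_score(self, triangle):
        z = pd.Series({"a": -1.0, "b": 0.0, "c": 1.0})
        assert score_network(triangle, z) == pytest.approx(0.0)

    def test_topology_factor(self, path3):
        z = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        # path: CCC of each node is 1 (each closed neighborhood is a clique
        # of size >= 2)... except the middle node whose neighborhood is the
        # whole path, density 2/3
        expected_ccc = (1.0 + 2.0 / 3.0 + 1.0) / 3.0
        assert score_network(path3, z) == pytest.approx(expected_ccc)


@pytest.fixture(scope="module")
def small_run(small_instance):
    net, stats, planted = small_instance
    config = AmendConfig(n=10, s=-1, eta0=0.5, seed=3)
    module, trace = run_amend(net, stats, config)
    return net, stats, planted, config, module, trace


class TestIterateOnce:
    def test_grid_maximum_equals_best_individual_arm(self, small_instance):
        net, stats, _ = small_instance
        config = AmendConfig(n=10, s=-1, eta0=0.5, seed=0)
        grid = [0.2, 0.5, 0.9]
        module, alpha = iterate_once(net, stats, 0.4, grid, config)
        arm_scores = {}
        for a in grid:
            m, _ = iterate_once(net, stats, 0.4, [a], config)
            arm_scores[a] = m.score
        assert module.score == pytest.approx(max(arm_scores.values()), abs=1e-12)
        assert alpha == min(a for a, s in arm_scores.items()
                            if s == pytest.approx(module.score, abs=1e-12))

    def test_k_zero_keeps_whole_network(self, small_instance):
        net, stats, _ = small_instance
        config = AmendConfig(n=10, s=-1, eta0=0.5, seed=0)
        module, _ = iterate_once(net, stats, 0.0, [0.5], config)
        assert len(module.nodes) >= net.n_nodes - 1


class TestRunAmend:
    def test_module_connected_and_score_is_trace_max(self, small_run):
        net, _, _, _, module, trace = small_run
        sub = net.graph.subgraph(module.nodes)
        import networkx as nx

        assert nx.is_connected(sub)
        assert module.score == pytest.approx(max(r.score for r in trace.records))

    def test_trace_sizes_strictly_shrink(self, small_run):
        *_, trace = small_run
        sizes = [len(r.nodes) for r in trace.records]
        assert all(b < a for a, b in zip(sizes, sizes[1:]))

    def test_trace_nested_node_sets(self, small_run):
        *_, trace = small_run
        sets = [set(r.nodes) for r in trace.records]
        assert all(b <= a for a, b in zip(sets, sets[1:]))

    def test_mean_z_non_decreasing(self, small_run):
        *_, trace = small_run
        mz = [r.mean_z for r in trace.records]
        assert all(b >= a - 1e-9 for a, b in zip(mz, mz[1:]))

    def test_planted_module_recovered(self, small_run):
        _, _, planted, _, module, _ = small_run
        assert jaccard(module.nodes, planted) >= 0.5

    def test_reproducible_given_seed(self, small_instance):
        net, stats, _ = small_instance
        config = AmendConfig(n=10, s=-1, eta0=0.5, seed=3)
        m1, t1 = run_amend(net, stats, config)
        m2, t2 = run_amend(net, stats, config)
        assert m1 == m2
        assert t1.records == t2.records

    def test_no_shared_genes_errors(self, small_instance):
        net, stats, _ = small_instance
        other = stats.copy()
        other.index = ["x" + g for g in other.index]
        with pytest.raises(ValueError):
            run_amend(net, other, AmendConfig(n=5, s=-1, eta0=0.5))


class TestOptimizeEta0:
    def test_single_particle_no_iterations_is_one_run(self, small_instance):
        net, stats, _ = small_instance
        config = AmendConfig(
            n=10, s=-1, eta0=None, seed=11,
            pso=PSOSettings(swarm_size=1, iterations=0),
        )
        eta0, module, trace = optimize_eta0(net, stats, config)
        direct, _ = run_amend(net, stats, config, eta0=round(eta0, 12))
        assert module.nodes == direct.nodes

    def test_deterministic_under_seed(self, small_instance):
        net, stats, _ = small_instance
        config = AmendConfig(
            n=10, s=-1, eta0=None, seed=5,
            pso=PSOSettings(swarm_size=3, iterations=2),
        )
        a = optimize_eta0(net, stats, config)
        b = optimize_eta0(net, stats, config)
        assert a[0] == b[0] and a[1].nodes == b[1].nodes

    def test_pso_at_least_as_good_as_coarse_grid(self, small_instance):
        net, stats, _ = small_instance
        config = AmendConfig(
            n=10, s=-1, eta0=None, seed=2,
            pso=PSOSettings(swarm_size=6, iterations=6),
        )
        _, module, _ = optimize_eta0(net, stats, config)
        grid_best = max(
            run_amend(net, stats, config, eta0=e)[0].score
            for e in (0.1, 0.3, 0.5, 0.7, 0.9)
        )
        assert module.score >= grid_best - 0.35 * abs(grid_best)
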