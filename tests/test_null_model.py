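import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
import hypothesis.strategies as st

from locmotif import (
    DirectedLabeledNetwork,
    NetworkSample,
    SwitchChainState,
    VertexLabelSet,
    attempt_edge_switch,
    degree_sequence,
    derive_seed,
    estimate_distinct_lower_bound,
    estimate_ensemble_size,
    estimate_mixing_parameter,
    generate_ensemble,
    gnp_null,
    mc_quantile,
    performance_index,
    randomize_network,
    select_representative,
)

from conftest import make_network, networks


class TestEdgeSwitch:
    def test_disjoint_pair_always_switches(self, two_disjoint_edges):
        state = SwitchChainState.from_network(two_disjoint_edges, seed=0)
        attempt_edge_switch(state)
        assert state.network.edges == frozenset({("A", "D"), ("C", "B")})
        assert state.switches_accepted == 1

    def test_reciprocal_pair_rejected(self):
        net = make_network(("A", "B"), {("A", "B"), ("B", "A")})
        state = SwitchChainState.from_network(net, seed=0)
        for _ in range(20):
            attempt_edge_switch(state)
        assert state.network == net
        assert state.attempts_made == 20 and state.switches_accepted == 0

    def test_shared_head_accepted_without_change(self):
        net = make_network(("A", "B", "C"), {("A", "B"), ("C", "B")})
        state = SwitchChainState.from_network(net, seed=0)
        attempt_edge_switch(state)
        assert state.network == net
        assert state.switches_accepted == 1

    def test_single_edge_chain_undefined(self):
        net = make_network(("A", "B"), {("A", "B")})
        with pytest.raises(ValueError, match="chain undefined"):
            SwitchChainState.from_network(net, seed=0)


class TestRandomizeNetwork:
    @given(networks(min_m=2), st.sampled_from([1, 3, 10]), st.integers(0, 2**31 - 1))
    @settings(max_examples=100)
    def test_degree_sequence_and_simplicity_preserved(self, net, Q, seed):
        out = randomize_network(net, Q, seed)
        assert degree_sequence(out) == degree_sequence(net)
        assert all(t != h for t, h in out.edges)  # loops impossible
        assert out.m == net.m  # frozenset: multi-edges impossible

    def test_q_zero_is_identity(self, four_cycle):
        assert randomize_network(four_cycle, 0, seed=1) == four_cycle

    def test_three_cycle_is_fixed_point(self, three_cycle):
        for seed in range(10):
            assert randomize_network(three_cycle, 100, seed) == three_cycle

    def test_too_few_edges_warns_and_returns_input(self):
        net = make_network(("A", "B"), {("A", "B")})
        with pytest.warns(UserWarning, match="cannot be randomized"):
            assert randomize_network(net, 10, seed=0) == net


class TestEnsemble:
    def test_deterministic_under_seed(self, four_cycle):
        e1 = generate_ensemble(four_cycle, M=3, Q=10, seed=42)
        e2 = generate_ensemble(four_cycle, M=3, Q=10, seed=42)
        assert e1.realizations == e2.realizations

    def test_three_cycle_ensemble_is_constant(self, three_cycle):
        ens = generate_ensemble(three_cycle, M=20, Q=50, seed=1)
        assert all(r == three_cycle for r in ens.realizations)

    def test_all_degree_sequences_identical(self):
        rng = np.random.default_rng(3)
        labels = tuple("ABCDEFGHI")
        pairs = [(a, b) for a in labels for b in labels if a != b]
        idx = rng.choice(len(pairs), size=30, replace=False)
        net = make_network(labels, {pairs[i] for i in idx})
        ens = generate_ensemble(net, M=50, Q=3, seed=9)
        want = degree_sequence(net)
        assert all(degree_sequence(r) == want for r in ens.realizations)


class TestRepresentative:
    def test_hand_computed_example(self, labels_abc):
        nets = [
            make_network(("A", "B", "C"), {("A", "B")}),
            make_network(("A", "B", "C"), {("A", "B"), ("B", "C")}),
            make_network(("A", "B", "C"), {("A", "B"), ("B", "C"), ("C", "A")}),
        ]
        sample = NetworkSample(nets[0].label_set, tuple(nets))
        assert select_representative(sample) == 1

    def test_identical_networks_tie_break_to_zero(self, three_cycle):
        sample = NetworkSample(three_cycle.label_set, (three_cycle,) * 4)
        assert select_representative(sample) == 0

    def test_singleton_sample(self, three_cycle):
        sample = NetworkSample(three_cycle.label_set, (three_cycle,))
        assert select_representative(sample) == 0


class TestPerformanceIndex:
    def test_exact_uniform_counts_give_zero(self):
        assert performance_index({"a": 2, "b": 2}, N=4, p0=0.5) == 0.0

    @pytest.mark.parametrize(
        "counts,expected", [({"a": 3, "b": 1}, 1.0), ({"a": 4}, 4.0)]
    )
    def test_two_category_examples(self, counts, expected):
        assert performance_index(counts, N=4, p0=0.5) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            performance_index({}, N=0, p0=0.5)
        with pytest.raises(ValueError):
            performance_index({}, N=4, p0=0.0)


class TestMcQuantile:
    def test_approaches_chi_squared_limit(self):
        # 2 equiprobable categories, large N: X^2 -> chi2 with 1 df
        q = mc_quantile(2, 10000, 0.5, alpha=0.05, reps=20000, seed=0)
        assert q == pytest.approx(scipy.stats.chi2.ppf(0.95, df=1), abs=0.15)

    def test_alpha_one_gives_minimum(self):
        q = mc_quantile(3, 30, 1 / 3, alpha=1.0, reps=500, seed=1)
        assert q >= 0.0

    def test_reproducible_under_seed(self):
        args = dict(num_categories=4, N=100, p0=0.25, alpha=0.1, reps=2000, seed=7)
        assert mc_quantile(**args) == mc_quantile(**args)


class TestDistinctLowerBound:
    def test_three_cycle_single_state(self, three_cycle):
        summary = estimate_distinct_lower_bound(three_cycle, [1, 10, 100], 30, seed=0)
        assert summary.distinct_count == 1

    def test_two_disjoint_edges_two_states(self, two_disjoint_edges):
        # all proposals are accepted, so the chain alternates deterministically:
        # pooling odd and even attempt counts reveals both states
        summary = estimate_distinct_lower_bound(two_disjoint_edges, [0.5, 1], 50, seed=0)
        assert summary.distinct_count == 2

    def test_q_zero_concentrates_on_input(self, four_cycle):
        summary = estimate_distinct_lower_bound(four_cycle, [0], 25, seed=0)
        assert summary.per_q_counts[0] == {four_cycle.key: 25}


class TestMixingParameter:
    def test_uniform_on_brute_forced_space(self, four_cycle):
        from oracles import digraphs_with_degree_sequence

        ds = degree_sequence(four_cycle)
        space = digraphs_with_degree_sequence(ds.labels, ds.in_deg, ds.out_deg)
        assert len(space) == 9  # fixed-point-free permutations of 4 elements
        report = estimate_mixing_parameter(
            four_cycle, [100], N_per_Q=450, alpha=0.05, reps=5000, seed=3
        )
        assert report.uniform
        assert report.num_categories == len(space)  # pooled ensemble covers the space

    def test_three_cycle_degenerate_single_category(self, three_cycle):
        report = estimate_mixing_parameter(three_cycle, [1, 10], 30, seed=0)
        assert report.uniform and report.num_categories == 1
        assert report.X2_per_Q == (0.0, 0.0)

    def test_frozen_chain_on_switchable_network_not_uniform(self, two_disjoint_edges):
        report = estimate_mixing_parameter(two_disjoint_edges, [0], 40, seed=0)
        assert not report.uniform
        assert report.chosen_Q == 0


class TestEnsembleSize:
    def test_degenerate_sample_accepts_smallest(self, three_cycle):
        sample = NetworkSample(three_cycle.label_set, (three_cycle,) * 3)
        assert estimate_ensemble_size(sample, 2, 10, [2, 4], B_max=8, epsilon=0.0, seed=0) == 2

    def test_epsilon_one_accepts_smallest(self, four_cycle):
        sample = NetworkSample(four_cycle.label_set, (four_cycle,) * 3)
        assert estimate_ensemble_size(sample, 2, 10, [2, 4], B_max=8, epsilon=1.0, seed=0) == 2

    def test_epsilon_zero_on_stochastic_ensemble_hits_b_max(self, four_cycle):
        sample = NetworkSample(four_cycle.label_set, (four_cycle,) * 3)
        assert estimate_ensemble_size(sample, 2, 10, [2, 4], B_max=40, epsilon=0.0, seed=0) == 40

    def test_grid_validation(self, four_cycle):
        sample = NetworkSample(four_cycle.label_set, (four_cycle,))
        with pytest.raises(ValueError):
            estimate_ensemble_size(sample, 2, 10, [4, 8], B_max=8, epsilon=0.1, seed=0)


class TestPoissonRandomGraphs:
    def test_gnm_preserves_edge_count_only(self):
        rng = np.random.default_rng(0)
        labels = tuple("ABCDEFGHI")
        pairs = [(a, b) for a in labels for b in labels if a != b]
        idx = rng.choice(len(pairs), size=20, replace=False)
        net = make_network(labels, {pairs[i] for i in idx})
        out = gnp_null(net, "gnm", seed=5)
        assert out.m == 20

    def test_gnp_edge_cases(self, labels_abc):
        empty = DirectedLabeledNetwork(labels_abc, frozenset())
        assert gnp_null(empty, "gnp", seed=0).m == 0
        full = make_network(
            ("A", "B", "C"), {(a, b) for a in "ABC" for b in "ABC" if a != b}
        )
        assert gnp_null(full, "gnp", seed=0).m == 6

    def test_gnp_mean_edge_count(self):
        labels = tuple("ABCDEFGHI")
        pairs = [(a, b) for a in labels for b in labels if a != b]
        net = make_network(labels, set(pairs[:24]))
        ms = [gnp_null(net, "gnp", seed=s).m for s in range(1000)]
        p = 24 / 72
        se = np.sqrt(72 * p * (1 - p))
        assert abs(np.mean(ms) - 24) <= 3 * se / np.sqrt(1000)

    def test_unknown_variant(self, four_cycle):
        with pytest.raises(ValueError, match="variant"):
            gnp_null(four_cycle, "stubs", seed=0)


def test_derive_seed_is_stable_and_32bit():
    a = derive_seed(1, "ens", 5)
    assert a == derive_seed(1, "ens", 5)
    assert 0 <= a < 2**32
    assert a != derive_seed(1, "ens", 6)
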