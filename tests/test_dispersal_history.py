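import math

import numpy as np
import pytest

from geopriorkit.geomodel import (DispersalModel, PriorSpec, build_rate_matrix,
                                  default_alphabet)
from geopriorkit.dispersal_history import (DispersalHistory, EventCountMatrix,
                                           count_events_by_pair,
                                           endpoint_conditioned_history,
                                           posterior_event_counts,
                                           sample_full_mapping,
                                           sample_node_states,
                                           simulate_history)
from geopriorkit.inference_mcmc import MCMCConfig, run_chain
from geopriorkit.likelihood_engine import (LikelihoodContext,
                                           transition_probabilities)
from geopriorkit.model_fit import parsimony_statistic
from geopriorkit.synth_fixtures import FixtureScenario, make_scenario
from geopriorkit.treedata_io import GeoAlphabet, TipAreas, parse_newick

from conftest import fixed_rates_priors


def _two_state_q(mu=1.0):
    m = DispersalModel(default_alphabet(2), True, np.ones(1), mu=mu)
    return build_rate_matrix(m).q


class TestEventCounting:
    def test_empty_history_zero_matrix(self):
        tree = parse_newick("(A:1,B:1);")
        hist = DispersalHistory(tree, k=2,
                                node_states=np.zeros(3, dtype=int))
        m = count_events_by_pair(hist)
        assert m.total == 0
        assert np.all(m.counts == 0)

    def test_hand_built_counts(self):
        # events p->q, q->p, p->q on a two-area alphabet (p=0, q=1)
        tree = parse_newick("(A:1,B:1);")
        tip_a, tip_b = tree.tip_indices
        states = np.zeros(3, dtype=int)
        states[tree.root] = 0
        states[tip_a] = 1
        states[tip_b] = 0
        hist = DispersalHistory(
            tree, k=2, node_states=states,
            branch_events={int(tip_a): [(0.2, 0, 1)],
                           int(tip_b): [(0.3, 0, 1), (0.6, 1, 0)]})
        hist.validate()
        m = count_events_by_pair(hist)
        assert np.array_equal(m.counts, [[0, 2], [1, 0]])
        assert m.total == 3
        assert m.total == sum(len(v) for v in hist.branch_events.values())

    def test_matrix_invariants(self):
        with pytest.raises(ValueError):
            EventCountMatrix(np.array([[1, 0], [0, 0]]))  # diagonal
        with pytest.raises(ValueError):
            EventCountMatrix(np.array([[0, -1], [0, 0]]))


class TestEndpointConditioned:
    def test_equal_endpoints_short_branch_empty(self):
        q = _two_state_q()
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert endpoint_conditioned_history(q, 1e-9, 0, 0, rng) == []

    def test_unequal_endpoints_at_least_one_event(self):
        q = _two_state_q()
        rng = np.random.default_rng(1)
        for _ in range(500):
            events = endpoint_conditioned_history(q, 0.7, 0, 1, rng)
            assert len(events) >= 1
            assert events[0][1] == 0 and events[-1][2] == 1

    def test_impossible_endpoints_rejected(self):
        # absorbing state 0: leaving it has probability zero
        q = np.array([[0.0, 0.0], [1.0, -1.0]])
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            endpoint_conditioned_history(q, 1.0, 0, 1, rng)

    def test_mean_count_matches_forward_filter_oracle(self):
        # independent oracle: forward Gillespie paths kept when they end in b
        q = _two_state_q()
        t, a, b = 1.0, 0, 1
        rng = np.random.default_rng(3)
        uni = np.array([len(endpoint_conditioned_history(q, t, a, b, rng))
                        for _ in range(50000)], dtype=float)
        fwd_rng = np.random.default_rng(4)
        fwd_counts = []
        while len(fwd_counts) < 20000:
            state, tau, n = a, 0.0, 0
            while True:
                tau += fwd_rng.exponential(1.0)  # |q_ii| = 1
                if tau >= t:
                    break
                state = 1 - state
                n += 1
            if state == b:
                fwd_counts.append(n)
        fwd = np.asarray(fwd_counts, dtype=float)
        se = math.sqrt(uni.var() / len(uni) + fwd.var() / len(fwd))
        assert abs(uni.mean() - fwd.mean()) < 3 * se

    def test_unconditional_marginalization_identity(self):
        # drawing endpoints from P(t) then endpoint-conditioned sampling must
        # reproduce unconditional event statistics: mean = rate * t
        q = _two_state_q(mu=1.3)
        t = 0.8
        p = transition_probabilities(q, t)
        rng = np.random.default_rng(5)
        n = 30000
        total = 0
        for _ in range(n):
            a = rng.integers(2)  # uniform = stationary for symmetric q
            b = rng.choice(2, p=p[a])
            total += len(endpoint_conditioned_history(q, t, a, b, rng, p_t=p))
        mean = total / n
        expected = 1.3 * t
        assert abs(mean - expected) < 3 * math.sqrt(expected / n) * 1.5


class TestNodeStateSampling:
    def test_zero_length_tree_forces_root_state(self):
        tree = parse_newick("((A:0,B:0):0,C:0);")
        alphabet = default_alphabet(2)
        model = DispersalModel(alphabet, True, np.ones(1), mu=1.0)
        tips = TipAreas({"A": "A", "B": "A", "C": "A"}, alphabet)
        ctx = LikelihoodContext(tree, tips, build_rate_matrix(model),
                                model.root_freqs)
        states = sample_node_states(ctx, np.random.default_rng(0))
        assert np.all(states == alphabet.index("A"))

    def test_root_distribution_matches_brute_force(self):
        tree = parse_newick("((A:0.4,B:0.9):0.3,C:0.7);")
        alphabet = default_alphabet(2)
        rng_q = np.random.default_rng(7)
        model = DispersalModel(alphabet, False, rng_q.uniform(0.2, 2.0, 2),
                               mu=0.8)
        q = build_rate_matrix(model)
        tips = TipAreas({"A": "A", "B": "B", "C": "A"}, alphabet)
        ctx = LikelihoodContext(tree, tips, q, model.root_freqs)
        # brute-force conditional root distribution
        pmats = {i: transition_probabilities(q, tree.blen[i])
                 for i in range(tree.n_nodes)}
        states = tips.bind(tree)
        internals = [i for i in range(tree.n_nodes) if tree.children[i]]
        joint = np.zeros(2)
        import itertools
        for assign in itertools.product(range(2), repeat=len(internals)):
            s = states.copy()
            for node, st in zip(internals, assign):
                s[node] = st
            term = model.root_freqs[s[tree.root]]
            for node in range(tree.n_nodes):
                if node != tree.root:
                    term *= pmats[node][s[tree.parent[node]], s[node]]
            joint[s[tree.root]] += term
        joint /= joint.sum()
        rng = np.random.default_rng(8)
        n = 20000
        draws = np.array([sample_node_states(ctx, rng)[tree.root]
                          for _ in range(n)])
        freq = (draws == 0).mean()
        se = math.sqrt(joint[0] * (1 - joint[0]) / n)
        assert abs(freq - joint[0]) < 3.5 * se

    def test_deterministic_under_seed(self, small_scenario):
        tree, tips, _ = small_scenario
        model = DispersalModel(default_alphabet(3), True, np.ones(3), mu=0.5)
        ctx = LikelihoodContext(tree, tips, build_rate_matrix(model),
                                model.root_freqs)
        s1 = sample_node_states(ctx, np.random.default_rng(9))
        s2 = sample_node_states(ctx, np.random.default_rng(9))
        assert np.array_equal(s1, s2)


class TestFullMapping:
    def _ctx(self, small_scenario):
        tree, tips, _ = small_scenario
        model = DispersalModel(default_alphabet(3), True, np.ones(3), mu=0.5)
        return (LikelihoodContext(tree, tips, build_rate_matrix(model),
                                  model.root_freqs), tree, tips)

    def test_mapping_respects_data_and_parsimony_floor(self, small_scenario):
        ctx, tree, tips = self._ctx(small_scenario)
        pars = parsimony_statistic(tree, tips)
        rng = np.random.default_rng(10)
        states = tips.bind(tree)
        for _ in range(100):
            hist = sample_full_mapping(ctx, rng)
            hist.validate()
            assert hist.total_events >= pars
            for i in tree.tip_indices:
                assert hist.node_states[i] == states[i]

    def test_unconditional_mean_events_is_mu_T(self, small_scenario):
        tree, _, _ = small_scenario
        mu = 0.5
        model = DispersalModel(default_alphabet(3), True, np.ones(3), mu=mu)
        rng = np.random.default_rng(11)
        counts = np.array([simulate_history(tree, model, rng).total_events
                           for _ in range(20000)], dtype=float)
        se = counts.std() / math.sqrt(len(counts))
        assert abs(counts.mean() - mu * tree.tree_length) < 3 * se


class TestPosteriorEventCounts:
    def test_monomorphic_low_rate_near_zero(self):
        tree, _, _ = make_scenario(FixtureScenario(n_tips=15, k=2, mu=0.5,
                                                   seed=1))
        alphabet = default_alphabet(2)
        tips = TipAreas({lbl: "A" for lbl in tree.tip_labels}, alphabet)
        priors = fixed_rates_priors(
            PriorSpec("exponential", "mu", {"rate": 50.0}))
        trace = run_chain(priors, (tree, tips),
                          MCMCConfig(n_iterations=3000, seed=2, thin=3)
                          ).burned(0.1)
        base = DispersalModel(alphabet, True, np.ones(1), mu=1.0)
        summ = posterior_event_counts(trace, tree, tips, n_draws=200, seed=3,
                                      base_model=base)
        assert summ.total_mean < 1.0

    def test_total_bounded_below_by_parsimony(self, small_scenario):
        tree, tips, _ = small_scenario
        priors = fixed_rates_priors(PriorSpec("exponential", "mu", {"rate": 1.0}))
        trace = run_chain(priors, (tree, tips),
                          MCMCConfig(n_iterations=3000, seed=4, thin=3)
                          ).burned(0.1)
        base = DispersalModel(default_alphabet(3), True, np.ones(3), mu=1.0)
        summ = posterior_event_counts(trace, tree, tips, n_draws=200, seed=5,
                                      base_model=base)
        pars = parsimony_statistic(tree, tips)
        assert np.all(summ.total_samples >= pars)
        assert summ.total_mean >= pars

    def test_recovers_simulated_truth_scale(self, small_scenario):
        # posterior mean total lies within the central 90% of the sampling
        # distribution of the true (simulated) totals
        tree, tips, _ = small_scenario
        model = DispersalModel(default_alphabet(3), True, np.ones(3), mu=0.5)
        rng = np.random.default_rng(6)
        truth_totals = np.array(
            [simulate_history(tree, model, rng).total_events
             for _ in range(500)])
        priors = fixed_rates_priors(PriorSpec("exponential", "mu", {"rate": 1.0}))
        trace = run_chain(priors, (tree, tips),
                          MCMCConfig(n_iterations=6000, seed=7, thin=6)
                          ).burned(0.1)
        base = DispersalModel(default_alphabet(3), True, np.ones(3), mu=1.0)
        summ = posterior_event_counts(trace, tree, tips, n_draws=300, seed=8,
                                      base_model=base)
        lo, hi = np.quantile(truth_totals, [0.05, 0.95])
        assert lo <= summ.total_mean <= hi

    def test_frame_output_shape(self, small_scenario):
        tree, tips, _ = small_scenario
        priors = fixed_rates_priors(PriorSpec("exponential", "mu", {"rate": 1.0}))
        trace = run_chain(priors, (tree, tips),
                          MCMCConfig(n_iterations=500, seed=9, thin=5))
        base = DispersalModel(default_alphabet(3), True, np.ones(3), mu=1.0)
        summ = posterior_event_counts(trace, tree, tips, n_draws=50, seed=10,
                                      base_model=base)
        df = summ.to_frame()
        assert len(df) == 6  # ordered pairs for k = 3
        assert set(df.columns) == {"from", "to", "mean", "hpd_lower",
                                   "hpd_upper"}
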