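import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from geopriorkit.geomodel import (DispersalModel, PriorSpec, build_rate_matrix,
                                  default_alphabet)
from geopriorkit.inference_mcmc import MCMCConfig, run_chain
from geopriorkit.likelihood_engine import transition_probabilities
from geopriorkit.model_fit import (PPSResult, PowerPosteriorLadder,
                                   bayes_factor, beta_schedule,
                                   parsimony_statistic, path_sampling_lnML,
                                   posterior_predictive_pvalue,
                                   quadrature_lnML_1d, run_power_posterior,
                                   simulate_tip_data, stepping_stone_lnML,
                                   tipwise_multinomial_statistic)
from geopriorkit.synth_fixtures import FixtureScenario, make_scenario
from geopriorkit.treedata_io import GeoAlphabet, TipAreas, Trace, parse_newick

from conftest import fixed_rates_priors


class TestSimulateTipData:
    def test_tiny_mu_monomorphic(self, small_scenario):
        tree, _, _ = small_scenario
        model = DispersalModel(default_alphabet(3), True, np.ones(3), mu=1e-9)
        tips = simulate_tip_data(tree, model, seed=0)
        assert len(set(tips.mapping.values())) == 1

    def test_same_seed_identical(self, small_scenario):
        tree, _, _ = small_scenario
        model = DispersalModel(default_alphabet(3), True, np.ones(3), mu=0.8)
        assert (simulate_tip_data(tree, model, seed=5).mapping
                == simulate_tip_data(tree, model, seed=5).mapping)

    def test_two_tip_marginals_match_transition_matrices(self):
        tree = parse_newick("(A:0.6,B:1.1);")
        rng = np.random.default_rng(3)
        model = DispersalModel(default_alphabet(2), False,
                               np.array([1.7, 0.4]), mu=0.9,
                               root_freqs=np.array([0.35, 0.65]))
        q = build_rate_matrix(model).q
        n = 20000
        counts = np.zeros(2)
        for _ in range(n):
            tips = simulate_tip_data(tree, model, rng=rng)
            counts[model.alphabet.index(tips.mapping["A"])] += 1
        p = transition_probabilities(q, 0.6)
        expected = model.root_freqs @ p
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(counts / n - expected) < 3.5 * se)


class TestSummaryStatistics:
    def test_parsimony_monomorphic_zero(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        alphabet = GeoAlphabet(("p", "q"))
        tips = TipAreas({"A": "p", "B": "p", "C": "p"}, alphabet)
        assert parsimony_statistic(tree, tips) == 0

    def test_parsimony_one_change(self):
        # exhaustively: labelings (p, q, p) on ((A,B),C) need exactly 1 change
        tree = parse_newick("((A:1,B:1):1,C:1);")
        alphabet = GeoAlphabet(("p", "q"))
        tips = TipAreas({"A": "p", "B": "q", "C": "p"}, alphabet)
        assert parsimony_statistic(tree, tips) == 1

    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_parsimony_ten_areas_floor(self, seed):
        tree, tips, _ = make_scenario(
            FixtureScenario(n_tips=10, k=10, mu=0.5, seed=seed,
                            one_tip_per_area=True))
        assert parsimony_statistic(tree, tips) == 9

    def test_multinomial_monomorphic_zero(self):
        alphabet = GeoAlphabet(("p", "q"))
        tips = TipAreas({f"t{i}": "p" for i in range(7)}, alphabet)
        assert tipwise_multinomial_statistic(tips) == pytest.approx(0.0)

    def test_multinomial_three_one_split(self):
        alphabet = GeoAlphabet(("p", "q"))
        tips = TipAreas({"a": "p", "b": "p", "c": "p", "d": "q"}, alphabet)
        expected = 3 * math.log(0.75) + math.log(0.25)
        assert tipwise_multinomial_statistic(tips) == pytest.approx(expected,
                                                                    abs=1e-4)

    def test_multinomial_label_permutation_invariant(self):
        alphabet = GeoAlphabet(("p", "q", "r"))
        t1 = TipAreas({"a": "p", "b": "p", "c": "q", "d": "r"}, alphabet)
        t2 = TipAreas({"a": "r", "b": "r", "c": "p", "d": "q"}, alphabet)
        assert (tipwise_multinomial_statistic(t1)
                == pytest.approx(tipwise_multinomial_statistic(t2)))


class TestPosteriorPredictive:
    def test_constant_statistic_two_sided_p_is_one(self, small_scenario):
        tree, tips, _ = small_scenario
        priors = fixed_rates_priors(PriorSpec("exponential", "mu", {"rate": 1.0}))
        trace = run_chain(priors, (tree, tips),
                          MCMCConfig(n_iterations=500, seed=1, thin=5))
        base = DispersalModel(default_alphabet(3), True, np.ones(3), mu=1.0)
        res = posterior_predictive_pvalue(
            trace, tree, tips, lambda t, x: 1.0, n_draws=50, seed=2,
            base_model=base)
        assert res.p_upper == pytest.approx(0.5)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_adequate_vs_concentrated_prior(self, small_scenario):
        # observed statistic inside the 95% predictive interval under a
        # reasonable prior, outside under a pathologically concentrated one
        tree, tips, _ = small_scenario
        base = DispersalModel(default_alphabet(3), True, np.ones(3), mu=1.0)
        good = fixed_rates_priors(PriorSpec("hierarchical_exponential", "mu"))
        bad = fixed_rates_priors(PriorSpec("fixed", "mu", {"value": 30.0}))
        results = {}
        for name, priors in [("good", good), ("bad", bad)]:
            trace = run_chain(priors, (tree, tips),
                              MCMCConfig(n_iterations=6000, seed=3, thin=5)
                              ).burned(0.1)
            results[name] = posterior_predictive_pvalue(
                trace, tree, tips, "parsimony", n_draws=300, seed=9,
                base_model=base)
        lo, hi = results["good"].predictive_interval(0.95)
        assert lo <= results["good"].observed <= hi
        lo, hi = results["bad"].predictive_interval(0.95)
        assert not lo <= results["bad"].observed <= hi

    def test_draw_count_validated(self, small_scenario):
        tree, tips, _ = small_scenario
        priors = fixed_rates_priors(PriorSpec("exponential", "mu", {"rate": 1.0}))
        trace = run_chain(priors, (tree, tips),
                          MCMCConfig(n_iterations=100, seed=1, thin=10))
        base = DispersalModel(default_alphabet(3), True, np.ones(3), mu=1.0)
        with pytest.raises(ValueError):
            posterior_predictive_pvalue(trace, tree, tips, "parsimony",
                                        n_draws=10 ** 6, seed=1,
                                        base_model=base)


class TestBetaSchedule:
    def test_endpoints(self):
        b = beta_schedule(8)
        assert b[0] == 0.0 and b[-1] == 1.0

    def test_known_value(self):
        b = beta_schedule(4, alpha=0.3)
        assert b[2] == pytest.approx(0.5 ** (1 / 0.3), rel=1e-12)
        assert b[2] == pytest.approx(0.09921, abs=5e-6)

    @given(st.integers(min_value=2, max_value=128))
    def test_strictly_increasing(self, k):
        assert np.all(np.diff(beta_schedule(k)) > 0)

    def test_too_few_stones(self):
        with pytest.raises(ValueError):
            beta_schedule(1)


def _constant_ladder(c, betas=(0.0, 0.25, 1.0), n=50):
    traces = []
    for i, b in enumerate(betas):
        df = pd.DataFrame({"state": np.arange(n),
                           "likelihood": np.full(n, float(c))})
        traces.append(Trace(df, beta=b))
    return PowerPosteriorLadder(betas=np.asarray(betas), traces=traces)


class TestMarginalLikelihoodEstimators:
    def test_constant_likelihood_exact(self):
        lad = _constant_ladder(-7.25)
        assert stepping_stone_lnML(lad) == pytest.approx(-7.25, abs=1e-12)
        assert path_sampling_lnML(lad) == pytest.approx(-7.25, abs=1e-12)

    def test_translation_identity(self, toy_1d):
        tree, tips, base, prior = toy_1d
        cfg = MCMCConfig(n_iterations=2000, seed=2, thin=2)
        lad = run_power_posterior(fixed_rates_priors(prior), (tree, tips), cfg,
                                  betas=beta_schedule(8))
        ss = stepping_stone_lnML(lad)
        shifted = PowerPosteriorLadder(
            betas=lad.betas,
            traces=[Trace(t.table.assign(likelihood=t["likelihood"] + 100.0),
                          beta=t.beta) for t in lad.traces])
        assert stepping_stone_lnML(shifted) == pytest.approx(ss + 100.0,
                                                             abs=1e-8)

    def test_ladder_validation(self):
        with pytest.raises(ValueError):
            _constant_ladder(0.0, betas=(0.0, 0.5, 0.9))   # must end at 1
        with pytest.raises(ValueError):
            _constant_ladder(0.0, betas=(0.0, 0.5, 0.5, 1.0))

    def test_estimators_agree_on_toy(self, toy_1d):
        tree, tips, base, prior = toy_1d
        cfg = MCMCConfig(n_iterations=3000, seed=4, thin=2)
        lad = run_power_posterior(fixed_rates_priors(prior), (tree, tips), cfg,
                                  betas=beta_schedule(16))
        assert stepping_stone_lnML(lad) == pytest.approx(
            path_sampling_lnML(lad), abs=0.2)


class TestBayesFactor:
    def test_identity_and_antisymmetry(self):
        assert bayes_factor(-3.0, -3.0) == 0.0
        assert bayes_factor(-1.0, -4.0) == -bayes_factor(-4.0, -1.0)

    def test_matches_quadrature_difference(self, toy_1d):
        tree, tips, base, p1 = toy_1d
        p2 = PriorSpec("exponential", "mu", {"rate": 5.0})
        quad_bf = (quadrature_lnML_1d(tree, tips, base, p1)
                   - quadrature_lnML_1d(tree, tips, base, p2))
        lads = []
        for seed, prior in [(11, p1), (12, p2)]:
            cfg = MCMCConfig(n_iterations=4000, seed=seed, thin=2)
            lads.append(run_power_posterior(
                fixed_rates_priors(prior), (tree, tips), cfg,
                betas=beta_schedule(16)))
        est = bayes_factor(stepping_stone_lnML(lads[0]),
                           stepping_stone_lnML(lads[1]))
        assert est == pytest.approx(quad_bf, abs=0.2)

    def test_infinite_input_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(float("-inf"), 0.0)


def test_pps_result_validates_pvalues():
    with pytest.raises(ValueError):
        PPSResult("s", 0.0, np.zeros(3), p_upper=1.5, p_two_sided=0.5)
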