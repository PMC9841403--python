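"""Model adequacy and model comparison for the discrete-geographic CTMC.

Absolute fit is assessed by posterior-predictive simulation: replicate
datasets are simulated from posterior draws and compared to the observed data
through summary statistics (defaults: the Fitch parsimony score of the
geographic character, and the multinomial log-likelihood of the tip-area
counts). Relative fit is assessed by marginal likelihoods estimated from a
ladder of power posteriors (stepping-stone and path-sampling estimators) and
compared through Bayes factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .geomodel import (DispersalModel, GeoAlphabet, PriorSpec,
                       build_rate_matrix, log_prior_density)
from .likelihood_engine import LikelihoodContext, PruningEngine, tree_log_likelihood
from .inference_mcmc import MCMCConfig, draws_from_trace, model_from_trace_row, run_chain
from .treedata_io import TimeTree, TipAreas, Trace, TreeSet, as_tree_set
from . import dispersal_history as _dh

Statistic = Callable[[TimeTree, TipAreas], float]


def simulate_tip_data(tree: TimeTree, model: DispersalModel,
                      seed: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None) -> TipAreas:
    """Simulate tip areas: root state from the root frequencies, then CTMC
    event simulation along every branch. Deterministic under ``seed``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    hist = _dh.simulate_history(tree, model, rng)
    mapping = {tree.labels[i]: model.alphabet.areas[hist.node_states[i]]
               for i in tree.tip_indices}
    return TipAreas(mapping=mapping, alphabet=model.alphabet)


def parsimony_statistic(tree: TimeTree, tips: TipAreas) -> int:
    """Fitch small-parsimony score of the geographic character.

    The minimum number of dispersal events consistent with the observed tip
    areas on the (binary) tree: one bottom-up pass taking set intersections
    where possible and unions (scoring one change) otherwise. A dataset whose
    tips occupy m distinct areas scores at least m - 1.
    """
    states = tips.bind(tree)
    sets: dict[int, int] = {}
    score = 0
    for node in tree.postorder:
        node = int(node)
        if not tree.children[node]:
            sets[node] = 1 << int(states[node])
            continue
        c1, c2 = tree.children[node]
        inter = sets[c1] & sets[c2]
        if inter:
            sets[node] = inter
        else:
            sets[node] = sets[c1] | sets[c2]
            score += 1
    return score


def tipwise_multinomial_statistic(tips: TipAreas) -> float:
    """Multinomial log-likelihood of the tip-area counts:
    ``sum_a n_a * ln(n_a / n)`` over occupied areas (0 when monomorphic)."""
    counts = np.asarray(list(tips.area_counts.values()), dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("no tips")
    return float(np.sum(counts * np.log(counts / n)))


DEFAULT_STATISTICS: dict[str, Statistic] = {
    "parsimony": lambda tree, tips: float(parsimony_statistic(tree, tips)),
    "multinomial": lambda tree, tips: tipwise_multinomial_statistic(tips),
}


@dataclass
class PPSResult:
    """Posterior-predictive check for one summary statistic."""

    statistic: str
    observed: float
    simulated: np.ndarray
    p_upper: float
    p_two_sided: float

    def __post_init__(self) -> None:
        self.simulated = np.asarray(self.simulated, dtype=float)
        for p in (self.p_upper, self.p_two_sided):
            if not 0.0 <= p <= 1.0:
                raise ValueError("p-values must lie in [0, 1]")

    def predictive_interval(self, probability: float = 0.95) -> tuple[float, float]:
        alpha = (1.0 - probability) / 2.0
        return (float(np.quantile(self.simulated, alpha)),
                float(np.quantile(self.simulated, 1.0 - alpha)))


def _midpoint_pvalues(simulated: np.ndarray, observed: float) -> tuple[float, float]:
    n = len(simulated)
    greater = float(np.sum(simulated > observed))
    ties = float(np.sum(simulated == observed))
    p_upper = (greater + 0.5 * ties) / n
    p_two = min(1.0, 2.0 * min(p_upper, 1.0 - p_upper))
    return p_upper, p_two


def posterior_predictive_pvalue(trace: Trace, trees, observed_tips: TipAreas,
                                statistic: Union[str, Statistic],
                                n_draws: int, seed: int,
                                base_model: DispersalModel) -> PPSResult:
    """Posterior-predictive p-value of a summary statistic.

    For each posterior draw (parameters + tree index) a replicate dataset is
    simulated and the statistic computed; ``p_upper`` is the fraction of
    simulated values >= the observed value with the midpoint tie rule, and the
    two-sided value is ``2 * min(p, 1-p)`` (capped at 1).
    """
    if isinstance(statistic, str):
        name, stat = statistic, DEFAULT_STATISTICS[statistic]
    else:
        name, stat = getattr(statistic, "__name__", "statistic"), statistic
    tree_set = as_tree_set(trees)
    rng = np.random.default_rng(seed)
    idx = draws_from_trace(trace, n_draws, rng)
    sims = np.empty(n_draws)
    obs_tree = tree_set[0]
    observed = float(stat(obs_tree, observed_tips))
    for out, row_i in enumerate(idx):
        row = trace.table.iloc[int(row_i)]
        model, ti = model_from_trace_row(row, base_model)
        sim_tips = simulate_tip_data(tree_set[ti], model, rng=rng)
        sims[out] = float(stat(tree_set[ti], sim_tips))
    p_upper, p_two = _midpoint_pvalues(sims, observed)
    return PPSResult(statistic=name, observed=observed, simulated=sims,
                     p_upper=p_upper, p_two_sided=p_two)


# ---------------------------------------------------------------------------
# Power posteriors / marginal likelihoods


def beta_schedule(n_stones: int, alpha: float = 0.3) -> np.ndarray:
    """Power ladder ``beta_j = (j / K)^(1/alpha)``, j = 0..K — quantiles of a
    Beta(alpha, 1) spacing, concentrating rungs near the prior."""
    if n_stones < 2:
        raise ValueError("need at least 2 stones")
    j = np.arange(n_stones + 1, dtype=float)
    return (j / n_stones) ** (1.0 / alpha)


@dataclass
class PowerPosteriorLadder:
    """Ordered power-posterior rungs with their traces."""

    betas: np.ndarray
    traces: list[Trace]

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.betas) != len(self.traces):
            raise ValueError("one trace per beta required")
        if np.any(np.diff(self.betas) <= 0):
            raise ValueError("betas must be strictly increasing")
        if self.betas[-1] != 1.0:
            raise ValueError("last beta must be 1")
        if self.betas[0] < 0:
            raise ValueError("betas must be >= 0")

    @property
    def mean_log_likelihood(self) -> np.ndarray:
        return np.asarray([t["likelihood"].mean() for t in self.traces])


def run_power_posterior(priors: dict, data: tuple, config: MCMCConfig,
                        betas: Optional[np.ndarray] = None,
                        burnin_fraction: float = 0.1,
                        symmetric: bool = True) -> PowerPosteriorLadder:
    """Run one chain per rung of the beta ladder (default: 32-stone
    Beta(0.3, 1) schedule); per-rung seeds derive from ``config.seed``."""
    if betas is None:
        betas = beta_schedule(32)
    betas = np.asarray(betas, dtype=float)
    traces = []
    for j, beta in enumerate(betas):
        cfg = MCMCConfig(
            n_iterations=config.n_iterations, seed=(config.seed * 100003 + j) % (2 ** 31),
            thin=config.thin, beta=float(beta),
            proposal_weights=dict(config.proposal_weights),
            tunings=dict(config.tunings),
            tree_jump_period=config.tree_jump_period)
        traces.append(run_chain(priors, data, cfg, symmetric=symmetric)
                      .burned(burnin_fraction))
    return PowerPosteriorLadder(betas=betas, traces=traces)


def stepping_stone_lnML(ladder: PowerPosteriorLadder) -> float:
    """Stepping-stone marginal-likelihood estimate.

    Each rung contributes ``ln (1/n) sum_i exp(dbeta * (l_i - l_max)) +
    dbeta * l_max`` using the log-likelihood samples of the lower rung
    (log-sum-exp stabilized).
    """
    total = 0.0
    for j in range(len(ladder.betas) - 1):
        dbeta = ladder.betas[j + 1] - ladder.betas[j]
        ll = ladder.traces[j]["likelihood"].astype(float)
        lmax = ll.max()
        total += math.log(np.mean(np.exp(dbeta * (ll - lmax)))) + dbeta * lmax
    return float(total)


def path_sampling_lnML(ladder: PowerPosteriorLadder) -> float:
    """Path-sampling (thermodynamic-integration) estimate: trapezoidal
    integral of the mean log-likelihood over beta."""
    return float(np.trapezoid(ladder.mean_log_likelihood, ladder.betas))


def bayes_factor(lnml_1: float, lnml_2: float) -> float:
    """Log Bayes factor ``ln BF = lnML_1 - lnML_2`` (reports conventionally
    also quote ``2 ln BF``)."""
    if not (math.isfinite(lnml_1) and math.isfinite(lnml_2)):
        raise ValueError("marginal likelihoods must be finite")
    return float(lnml_1 - lnml_2)


def quadrature_lnML_1d(tree: TimeTree, tips: TipAreas, base_model: DispersalModel,
                       mu_prior: PriorSpec, n_grid: int = 10000,
                       mu_bounds: tuple[float, float] = (1e-8, 50.0)) -> float:
    """Numerical-integration oracle for 1-D problems (rates fixed, prior on mu
    only): ``ln integral prior(mu) L(mu) dmu`` on a log-spaced grid."""
    T = tree.tree_length
    mus = np.geomspace(mu_bounds[0], mu_bounds[1], n_grid)
    engine = PruningEngine(tree, tips.bind(tree), base_model.k)
    from .likelihood_engine import EigenQ, branch_transition_matrices
    q_unit = build_rate_matrix(
        DispersalModel(base_model.alphabet, base_model.symmetric,
                       base_model.rel_rates, mu=1.0,
                       root_freqs=base_model.root_freqs)).q
    eig = EigenQ.decompose(q_unit)
    logf = np.empty(n_grid)
    for i, mu in enumerate(mus):
        pmats = branch_transition_matrices(q_unit, tree.blen, eig=eig, mult=mu)
        ll = engine.log_likelihood(pmats, base_model.root_freqs)
        logf[i] = log_prior_density(mu_prior, mu, T=T) + ll
    # trapezoid in log-mu coordinates: integrand f(mu) * mu d(log mu)
    logg = logf + np.log(mus)
    m = logg.max()
    vals = np.exp(logg - m)
    integral = np.trapezoid(vals, np.log(mus))
    return float(m + math.log(integral))
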