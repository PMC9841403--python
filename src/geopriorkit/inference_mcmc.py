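"""Metropolis-Hastings sampler targeting prior x likelihood^beta, plus
trace diagnostics (ESS, HPD intervals, summaries).

The joint state is (mu, relative rates, optional hierarchical-prior rate
lambda, tree index). Proposal kernels are multiplicative scale moves on each
positive scalar block and a uniform tree-jump over the supplied tree set; no
adaptive tuning is performed by default so a chain is a pure function of its
seed. Phylogenetic uncertainty is marginalized by treating the tree index as a
uniformly distributed nuisance parameter over a posterior sample of trees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geomodel import (DispersalModel, GeoAlphabet, ModelState, PriorSpec,
                       _hier_hyper, build_rate_matrix, count_free_rate_parameters,
                       log_prior_density, rate_pair_labels, sample_from_prior)
from .likelihood_engine import EigenQ, PruningEngine, branch_transition_matrices
from .treedata_io import TimeTree, TipAreas, Trace, TreeSet, as_tree_set


@dataclass
class MCMCConfig:
    """Chain controls: length, thinning, likelihood power beta, proposals."""

    n_iterations: int
    seed: int
    thin: int = 1
    beta: float = 1.0
    proposal_weights: dict = field(
        default_factory=lambda: {"mu": 3.0, "rel_rates": 1.0, "hyper": 1.0})
    tunings: dict = field(
        default_factory=lambda: {"mu": 2.0, "rel_rates": 2.0, "hyper": 2.0})
    tree_jump_period: int = 1

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be > 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.tree_jump_period < 1:
            raise ValueError("tree_jump_period must be >= 1")
        if not any(w > 0 for w in self.proposal_weights.values()):
            raise ValueError("proposal weights must not all be zero")


def scale_proposal(value: float, tuning: float,
                   rng: np.random.Generator) -> tuple[float, float]:
    """Multiplicative scale move: m = exp(tuning*(u-0.5)); Hastings log-ratio log m."""
    u = rng.random()
    m = math.exp(tuning * (u - 0.5))
    return value * m, math.log(m)


def tree_jump_proposal(state: ModelState, tree_set: TreeSet,
                       rng: np.random.Generator) -> tuple[int, float]:
    """Uniform draw over tree indices; symmetric, Hastings log-ratio 0."""
    return int(rng.integers(len(tree_set))), 0.0


class _GeoTarget:
    """log(prior) + beta*log(likelihood) with per-tree eigendecomposition cache."""

    def __init__(self, priors: dict, tree_set: TreeSet,
                 tips: Union[TipAreas, Sequence[TipAreas]],
                 beta: float, symmetric: bool):
        characters = (tips,) if isinstance(tips, TipAreas) else tuple(tips)
        self.priors = priors
        self.tree_set = tree_set
        self.beta = beta
        self.symmetric = symmetric
        self.alphabet = characters[0].alphabet
        self.k = self.alphabet.k
        self.pi = np.full(self.k, 1.0 / self.k)
        self.T = [t.tree_length for t in tree_set]
        self.Tbar = float(np.mean(self.T))
        self.engines = [[PruningEngine(t, ch.bind(t), self.k)
                         for ch in characters] for t in tree_set]
        self._eig_cache: dict[int, tuple[bytes, Optional[EigenQ]]] = {}

    def log_prior(self, state: ModelState, tree_index: Optional[int] = None) -> float:
        ti = state.tree_index if tree_index is None else tree_index
        mu_spec: PriorSpec = self.priors["mu"]
        if mu_spec.family == "hierarchical_exponential":
            lam = state.hyper_lambda
            a, b = _hier_hyper(mu_spec, self.Tbar)
            lp = (math.log(lam) - lam * state.mu  # mu | lambda ~ Exp(lambda)
                  + (a - 1.0) * math.log(lam) - b * lam
                  + a * math.log(b) - math.lgamma(a))
        else:
            lp = log_prior_density(mu_spec, state.mu, T=self.T[ti])
        rr_spec: PriorSpec = self.priors.get(
            "rel_rates", PriorSpec("exponential", "rel_rates", {"rate": 1.0}))
        if rr_spec.family != "fixed":
            for r in state.rel_rates:
                lp += log_prior_density(rr_spec, r)
        return lp

    def _q_unit(self, state: ModelState) -> np.ndarray:
        model = DispersalModel(self.alphabet, self.symmetric,
                               state.rel_rates, mu=1.0, root_freqs=self.pi)
        return build_rate_matrix(model).q

    def log_likelihood(self, state: ModelState) -> float:
        """Plain (beta=1) log-likelihood at the state's tree."""
        ti = state.tree_index
        q_unit = self._q_unit(state)
        key = q_unit.tobytes()
        cached = self._eig_cache.get(ti)
        if cached is None or cached[0] != key:
            cached = (key, EigenQ.decompose(q_unit))
            self._eig_cache[ti] = cached
        eig = cached[1]
        tree = self.tree_set[ti]
        pmats = branch_transition_matrices(q_unit, tree.blen, eig=eig,
                                           mult=state.mu)
        return sum(e.log_likelihood(pmats, self.pi) for e in self.engines[ti])


def run_chain(priors: dict, data: tuple, config: MCMCConfig,
              symmetric: bool = True) -> Trace:
    """Run a Metropolis-Hastings chain targeting prior x likelihood^beta.

    Parameters
    ----------
    priors : dict
        Maps ``"mu"`` (and optionally ``"rel_rates"``) to :class:`PriorSpec`.
    data : (TreeSet | TimeTree, TipAreas)
        The fixed tree(s) and the observed tip areas.
    config : MCMCConfig
        Chain controls; ``config.beta`` is the power on the likelihood.

    Returns
    -------
    Trace
        One row per thinned iteration with columns ``state``, ``posterior``,
        ``likelihood`` (plain, unpowered log-likelihood), ``mu``, one column
        per free relative rate, ``lambda`` under the hierarchical prior, and
        ``tree_index``. Identical seeds give identical traces.
    """
    trees, tips = data
    tree_set = as_tree_set(trees)
    target = _GeoTarget(priors, tree_set, tips, config.beta, symmetric)
    rng = np.random.default_rng(config.seed)
    beta = config.beta

    state = sample_from_prior(priors, target.alphabet, T=target.Tbar,
                              rng=rng, symmetric=symmetric)
    state.tree_index = 0

    mu_spec: PriorSpec = priors["mu"]
    rr_spec: PriorSpec = priors.get(
        "rel_rates", PriorSpec("exponential", "rel_rates", {"rate": 1.0}))
    hierarchical = mu_spec.family == "hierarchical_exponential"

    blocks = []
    if mu_spec.family != "fixed":
        blocks.append("mu")
    if rr_spec.family != "fixed" and len(state.rel_rates) > 0:
        blocks.append("rel_rates")
    if hierarchical:
        blocks.append("hyper")
    weights = np.array([max(config.proposal_weights.get(b, 1.0), 0.0)
                        for b in blocks])
    if blocks and weights.sum() == 0:
        weights = np.ones(len(blocks))
    probs = weights / weights.sum() if blocks else None

    lp = target.log_prior(state)
    ll = target.log_likelihood(state) if beta > 0 else None
    n_proposed = {b: 0 for b in blocks + ["tree"]}
    n_accepted = {b: 0 for b in blocks + ["tree"]}

    rate_cols = rate_pair_labels(target.alphabet, symmetric) \
        if rr_spec.family != "fixed" else []
    records = []

    def record(it: int) -> None:
        nonlocal ll
        row = {"state": it}
        ll_now = ll if ll is not None else target.log_likelihood(state)
        row["posterior"] = lp + beta * ll_now
        row["likelihood"] = ll_now
        row["mu"] = state.mu
        for name, val in zip(rate_cols, state.rel_rates):
            row[name] = val
        if hierarchical:
            row["lambda"] = state.hyper_lambda
        row["tree_index"] = state.tree_index
        records.append(row)

    record(0)
    for it in range(1, config.n_iterations + 1):
        if blocks:
            block = blocks[int(rng.choice(len(blocks), p=probs))]
            n_proposed[block] += 1
            tuning = config.tunings.get(block, 2.0)
            if block == "mu":
                new_mu, lhr = scale_proposal(state.mu, tuning, rng)
                cand = ModelState(new_mu, state.rel_rates, state.hyper_lambda,
                                  state.tree_index)
                cand_lp = target.log_prior(cand)
                cand_ll = ll
                if beta > 0:
                    cand_ll = target.log_likelihood(cand)
                    delta = (cand_lp - lp) + beta * (cand_ll - ll)
                else:
                    delta = cand_lp - lp
                if delta + lhr >= 0 or rng.random() < math.exp(delta + lhr):
                    state, lp, ll = cand, cand_lp, cand_ll
                    n_accepted[block] += 1
            elif block == "rel_rates":
                i = int(rng.integers(len(state.rel_rates)))
                new_rates = state.rel_rates.copy()
                new_rates[i], lhr = scale_proposal(new_rates[i], tuning, rng)
                cand = ModelState(state.mu, new_rates, state.hyper_lambda,
                                  state.tree_index)
                cand_lp = target.log_prior(cand)
                cand_ll = ll
                if beta > 0:
                    cand_ll = target.log_likelihood(cand)
                    delta = (cand_lp - lp) + beta * (cand_ll - ll)
                else:
                    delta = cand_lp - lp
                if delta + lhr >= 0 or rng.random() < math.exp(delta + lhr):
                    state, lp, ll = cand, cand_lp, cand_ll
                    n_accepted[block] += 1
            else:  # hyper lambda: likelihood unaffected
                new_lam, lhr = scale_proposal(state.hyper_lambda, tuning, rng)
                cand = ModelState(state.mu, state.rel_rates, new_lam,
                                  state.tree_index)
                cand_lp = target.log_prior(cand)
                delta = cand_lp - lp
                if delta + lhr >= 0 or rng.random() < math.exp(delta + lhr):
                    state, lp = cand, cand_lp
                    n_accepted[block] += 1
        if len(tree_set) > 1 and it % config.tree_jump_period == 0:
            n_proposed["tree"] += 1
            new_ti, lhr = tree_jump_proposal(state, tree_set, rng)
            if new_ti != state.tree_index:
                cand = ModelState(state.mu, state.rel_rates, state.hyper_lambda,
                                  new_ti)
                cand_lp = target.log_prior(cand)
                cand_ll = ll
                if beta > 0:
                    cand_ll = target.log_likelihood(cand)
                    delta = (cand_lp - lp) + beta * (cand_ll - ll)
                else:
                    delta = cand_lp - lp
                if delta + lhr >= 0 or rng.random() < math.exp(delta + lhr):
                    state, lp, ll = cand, cand_lp, cand_ll
                    n_accepted["tree"] += 1
            else:
                n_accepted["tree"] += 1
        if it % config.thin == 0:
            record(it)

    for block in blocks:
        if n_proposed[block] > 100 and n_accepted[block] == 0:
            warnings.warn(
                f"no accepted proposals for block {block!r} "
                f"({n_proposed[block]} attempts)", RuntimeWarning)
    return Trace(pd.DataFrame.from_records(records), beta=beta)


# ---------------------------------------------------------------------------
# Diagnostics


def effective_sample_size(series: np.ndarray) -> float:
    """ESS = N / (1 + 2 sum rho_t), initial-positive-sequence truncation.

    Lag autocorrelations are accumulated in pairs (rho_1+rho_2, rho_3+rho_4,
    ...) until the first nonpositive pair. A constant series has no
    autocorrelation structure; by convention its ESS is N (with a warning).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(f"series too short for ESS ({n} < 10)")
    var = x.var()
    if var == 0:
        warnings.warn("degenerate (constant) series: ESS set to N", RuntimeWarning)
        return float(n)
    xc = x - x.mean()
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        s += pair
        t += 2
    return float(n / (1.0 + 2.0 * s))


def hpd_interval(samples: np.ndarray, probability: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ceil(probability * N) sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    m = int(math.ceil(probability * n))
    m = min(max(m, 1), n)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def summarize_trace(trace: Trace, probability: float = 0.95,
                    burnin_fraction: float = 0.0) -> pd.DataFrame:
    """Per-parameter mean, variance, HPD interval and ESS.

    Returns a DataFrame indexed by parameter name with columns ``mean``,
    ``variance``, ``hpd_lower``, ``hpd_upper``, ``ess``.
    """
    tr = trace.burned(burnin_fraction) if burnin_fraction > 0 else trace
    if len(tr) == 0:
        raise ValueError("empty trace")
    rows = {}
    for col in tr.parameters:
        x = tr[col].astype(float)
        lo, hi = hpd_interval(x, probability)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ess = effective_sample_size(x) if len(x) >= 10 else float(len(x))
        rows[col] = {"mean": float(x.mean()), "variance": float(x.var(ddof=1))
                     if len(x) > 1 else 0.0,
                     "hpd_lower": lo, "hpd_upper": hi, "ess": ess}
    return pd.DataFrame.from_dict(rows, orient="index")


def draws_from_trace(trace: Trace, n_draws: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Row indices of posterior draws sampled without replacement."""
    n = len(trace)
    if n_draws > n:
        raise ValueError(f"n_draws={n_draws} exceeds trace length {n}")
    idx = rng.choice(n, size=n_draws, replace=False)
    return np.sort(idx)


def model_from_trace_row(row: "pd.Series", base_model: DispersalModel) -> tuple[DispersalModel, int]:
    """Rebuild a dispersal model from one trace row.

    Columns present in the trace (``mu``, ``rate_*``) override the base model;
    absent blocks (e.g. rates fixed during sampling) fall back to it. Returns
    the model and the row's tree index (0 when not recorded).
    """
    mu = float(row["mu"]) if "mu" in row.index else base_model.mu
    labels = rate_pair_labels(base_model.alphabet, base_model.symmetric)
    if all(name in row.index for name in labels):
        rel = np.asarray([float(row[name]) for name in labels])
    else:
        rel = base_model.rel_rates
    model = DispersalModel(base_model.alphabet, base_model.symmetric, rel,
                           mu=mu, root_freqs=base_model.root_freqs)
    ti = int(row["tree_index"]) if "tree_index" in row.index else 0
    return model, ti
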