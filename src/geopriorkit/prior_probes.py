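"""Prior-diagnosis instruments: robust-Bayes prior sweeps, data cloning, and
the induced prior on the number of dispersal events.

Robust Bayesian inference re-runs the same analysis under a set of candidate
priors and compares the resulting marginal posteriors; if they differ
materially, the inference is prior sensitive. Data cloning probes a *single*
prior: the likelihood is raised to an integer power beta (equivalent to
analyzing beta copies of the dataset), and as beta grows the posterior
concentrates on the maximum-likelihood estimate — so the trajectory of the
posterior mean across beta in {1, 5, 20} reveals how far the prior pulls the
posterior away from the data. The induced event-count prior translates a prior
on the dispersal rate mu into its implication for the number of dispersal
events on the tree, a scale on which minimal knowledge exists (data occupying
m areas require at least m - 1 events).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geomodel import (DispersalModel, GeoAlphabet, PriorSpec,
                       build_rate_matrix, sample_from_prior)
from .inference_mcmc import (MCMCConfig, effective_sample_size, hpd_interval,
                             run_chain, summarize_trace)
from .likelihood_engine import EigenQ, PruningEngine, branch_transition_matrices
from .treedata_io import TimeTree, TipAreas, Trace, TreeSet, as_tree_set
from . import dispersal_history as _dh


def _child_seed(seed: int, *indices: int) -> int:
    s = seed
    for i in indices:
        s = (s * 9176 + 7919 * (i + 1)) % (2 ** 31)
    return s


# ---------------------------------------------------------------------------
# Robust Bayesian prior sweeps


@dataclass
class RobustBayesDesign:
    """A sweep of named prior configurations over one fixed dataset."""

    priors: dict[str, dict]          # name -> {"mu": PriorSpec, ...}
    config: MCMCConfig
    replicates: int = 2
    symmetric: bool = True

    def __post_init__(self) -> None:
        if len(self.priors) < 2:
            raise ValueError("a robust-Bayes design needs >= 2 prior configurations")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class RobustBayesResult:
    traces: dict[tuple[str, int], Trace]
    summary: pd.DataFrame            # rows: (prior, replicate) x parameters
    overlap: pd.DataFrame            # pairwise HPD-overlap for mu
    sensitive: bool
    low_ess: list[tuple[str, int, str]]


def hpd_overlap(interval_1: tuple[float, float],
                interval_2: tuple[float, float]) -> float:
    """Overlap coefficient of two HPD intervals:
    ``|I1 ∩ I2| / min(|I1|, |I2|)`` (1 when nested, 0 when disjoint)."""
    lo = max(interval_1[0], interval_2[0])
    hi = min(interval_1[1], interval_2[1])
    inter = max(0.0, hi - lo)
    shorter = min(interval_1[1] - interval_1[0], interval_2[1] - interval_2[0])
    if shorter <= 0:
        return 1.0 if inter >= 0 and interval_1[0] <= interval_2[1] \
            and interval_2[0] <= interval_1[1] else 0.0
    return inter / shorter


SENSITIVITY_OVERLAP_THRESHOLD = 0.35
ESS_FLOOR = 100.0


def run_robust_bayes(design: RobustBayesDesign, data: tuple,
                     burnin_fraction: float = 0.1) -> RobustBayesResult:
    """Run every (prior configuration, replicate) cell on the shared dataset.

    All cells use identical data and chain settings; replicate seeds derive
    from the shared config seed. The result flags prior sensitivity when any
    pair of prior configurations has mu-HPD overlap below
    ``SENSITIVITY_OVERLAP_THRESHOLD``, and lists cells whose ESS fell below
    ``ESS_FLOOR`` (flagged, never dropped).
    """
    traces: dict[tuple[str, int], Trace] = {}
    rows = []
    low_ess: list[tuple[str, int, str]] = []
    for pi, (name, priors) in enumerate(design.priors.items()):
        for rep in range(design.replicates):
            cfg = MCMCConfig(
                n_iterations=design.config.n_iterations,
                seed=_child_seed(design.config.seed, pi, rep),
                thin=design.config.thin, beta=design.config.beta,
                proposal_weights=dict(design.config.proposal_weights),
                tunings=dict(design.config.tunings),
                tree_jump_period=design.config.tree_jump_period)
            trace = run_chain(priors, data, cfg, symmetric=design.symmetric)
            trace = trace.burned(burnin_fraction)
            traces[(name, rep)] = trace
            summ = summarize_trace(trace)
            for param, prow in summ.iterrows():
                rows.append({"prior": name, "replicate": rep, "parameter": param,
                             **prow.to_dict()})
                if param == "mu" and prow["ess"] < ESS_FLOOR:
                    low_ess.append((name, rep, param))
    summary = pd.DataFrame(rows)
    # pool replicates per prior for the mu overlap comparison
    names = list(design.priors)
    mu_hpds = {}
    for name in names:
        pooled = np.concatenate([traces[(name, r)]["mu"]
                                 for r in range(design.replicates)])
        mu_hpds[name] = hpd_interval(pooled)
    ov_rows = []
    sensitive = False
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ov = hpd_overlap(mu_hpds[a], mu_hpds[b])
            ov_rows.append({"prior_1": a, "prior_2": b, "overlap": ov})
            if ov < SENSITIVITY_OVERLAP_THRESHOLD:
                sensitive = True
    return RobustBayesResult(traces=traces, summary=summary,
                             overlap=pd.DataFrame(ov_rows),
                             sensitive=sensitive, low_ess=low_ess)


# ---------------------------------------------------------------------------
# Data cloning


@dataclass
class CloningDesign:
    """Data-cloning schedule: integer likelihood powers (clone counts)."""

    clone_counts: Sequence[int] = (0, 1, 5, 20)
    priors: dict = None
    replicates: int = 1

    def __post_init__(self) -> None:
        counts = list(self.clone_counts)
        if len(set(counts)) != len(counts):
            raise ValueError("clone counts must be distinct")
        if sorted(counts) != counts:
            raise ValueError("clone counts must be sorted")
        if 1 not in counts:
            raise ValueError("clone counts must include 1 (the plain posterior)")
        if any(c < 0 for c in counts):
            raise ValueError("clone counts must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        self.clone_counts = tuple(counts)


@dataclass
class CloningResult:
    traces: dict[tuple[int, int], Trace]   # (beta, replicate) -> trace
    summary: pd.DataFrame                  # beta, replicate, mean, variance, beta*variance


def run_data_cloning(design: CloningDesign, data: tuple, config: MCMCConfig,
                     symmetric: bool = True,
                     burnin_fraction: float = 0.1) -> CloningResult:
    """One powered chain per clone count (likelihood^beta with integer beta).

    Cloning is implemented by powering the log-likelihood — exact for this
    model since the likelihood of beta literal copies of the single geographic
    character is the beta-th power of the original likelihood. The summary
    tracks the posterior mean and variance of mu per clone count: convergence
    of the mean (toward the MLE) and the shrinking of ``beta * variance``
    diagnose the prior's contribution.
    """
    traces: dict[tuple[int, int], Trace] = {}
    rows = []
    for bi, beta in enumerate(design.clone_counts):
        for rep in range(design.replicates):
            cfg = MCMCConfig(
                n_iterations=config.n_iterations,
                seed=_child_seed(config.seed, bi, rep),
                thin=config.thin, beta=float(beta),
                proposal_weights=dict(config.proposal_weights),
                tunings=dict(config.tunings),
                tree_jump_period=config.tree_jump_period)
            trace = run_chain(design.priors, data, cfg,
                              symmetric=symmetric).burned(burnin_fraction)
            traces[(beta, rep)] = trace
            mu = trace["mu"]
            rows.append({"beta": beta, "replicate": rep,
                         "mean": float(mu.mean()),
                         "variance": float(mu.var(ddof=1)),
                         "beta_variance": beta * float(mu.var(ddof=1))})
    return CloningResult(traces=traces, summary=pd.DataFrame(rows))


def plot_cloning_summary(results: dict[str, CloningResult], path: Optional[str] = None):
    """One panel per prior configuration: boxplots of the mu samples per clone
    count, replicates side by side (the robust-Bayes/data-cloning figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(results), figsize=(5 * len(results), 4),
                             squeeze=False)
    for ax, (name, res) in zip(axes[0], results.items()):
        data, labels = [], []
        for (beta, rep), trace in sorted(res.traces.items()):
            data.append(trace["mu"])
            labels.append(f"{beta}\n(r{rep})")
        ax.boxplot(data, tick_labels=labels, showfliers=False)
        ax.set_title(name)
        ax.set_xlabel("clones (beta)")
        ax.set_ylabel("mu")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Grid MLE


def grid_mle(tips, tree: TimeTree, base_model: DispersalModel,
             mu_bounds: tuple[float, float] = (1e-6, 1e3),
             n_coarse: int = 200, rel_width: float = 1e-4) -> float:
    """Maximum-likelihood estimate of mu on a refined log-spaced grid.

    ``tips`` may be a single :class:`TipAreas` or a sequence of independent
    characters (their log-likelihoods add). Relative rates are held fixed at
    the base model's values (the 1-D profile). The coarse grid is iteratively
    zoomed until the bracketing interval has relative width below
    ``rel_width``. A flat likelihood (e.g. a dataset with no time depth
    carries no information about mu) triggers a warning and returns the lower
    boundary.
    """
    characters = (tips,) if isinstance(tips, TipAreas) else tuple(tips)
    engines = [PruningEngine(tree, ch.bind(tree), base_model.k)
               for ch in characters]
    q_unit = build_rate_matrix(
        DispersalModel(base_model.alphabet, base_model.symmetric,
                       base_model.rel_rates, mu=1.0,
                       root_freqs=base_model.root_freqs)).q
    eig = EigenQ.decompose(q_unit)

    def ll(mu: float) -> float:
        pmats = branch_transition_matrices(q_unit, tree.blen, eig=eig, mult=mu)
        return sum(e.log_likelihood(pmats, base_model.root_freqs)
                   for e in engines)

    lo, hi = mu_bounds
    while True:
        grid = np.geomspace(lo, hi, n_coarse)
        vals = np.asarray([ll(m) for m in grid])
        if vals.max() - vals.min() < 1e-10:
            warnings.warn("flat likelihood surface: mu is not identifiable "
                          f"(returning boundary {mu_bounds[0]})", RuntimeWarning)
            return float(mu_bounds[0])
        i = int(np.argmax(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if (hi - lo) / grid[i] < rel_width:
            return float(grid[i])


# ---------------------------------------------------------------------------
# Induced prior on the number of dispersal events


@dataclass
class EventCountPrior:
    """Empirical induced prior on the total number of dispersal events."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    def quantiles(self, probs=(0.025, 0.25, 0.5, 0.75, 0.975)) -> dict[float, float]:
        return {float(p): float(np.quantile(self.counts, p)) for p in probs}

    def fraction_below(self, floor: int) -> float:
        """Prior mass below a hard lower bound on the event count (a dataset
        occupying m areas requires at least m - 1 events, so mass below m - 1
        is wasted on impossible histories)."""
        return float(np.mean(self.counts < floor))


def induced_event_count_prior(priors: dict, tree: TimeTree, n_sims: int,
                              seed: int, alphabet: GeoAlphabet,
                              symmetric: bool = True) -> EventCountPrior:
    """Push a prior on (mu, rates) through the tree to an event-count prior.

    Each draw samples a model from the prior, simulates one unconditioned CTMC
    history over the whole tree, and counts its dispersal events. Under a
    fixed mu with stationary root frequencies the mean count is mu * T.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    T = tree.tree_length
    counts = np.empty(n_sims, dtype=np.int64)
    for i in range(n_sims):
        st = sample_from_prior(priors, alphabet, T=T, rng=rng,
                               symmetric=symmetric)
        model = DispersalModel(alphabet, symmetric, st.rel_rates, mu=st.mu)
        hist = _dh.simulate_history(tree, model, rng)
        counts[i] = hist.total_events
    return EventCountPrior(counts=counts)
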