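"""Stochastic mapping of dispersal histories and per-pair event counts.

A dispersal history is a full realization of the CTMC on the tree: a state at
every node plus an ordered list of (time, from-area, to-area) events on every
branch. Histories are sampled two ways:

* unconditionally (forward simulation from the root) — used for the induced
  prior on event counts and for posterior-predictive simulation; and
* conditionally on observed tip areas — node states are drawn jointly from
  their exact conditional distribution (pruning partials + preorder sampling),
  then each branch is filled in by endpoint-conditioned path sampling via
  uniformization (robust on short branches with unequal endpoints, where
  naive rejection sampling stalls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geomodel import DispersalModel, RateMatrix, build_rate_matrix
from .inference_mcmc import draws_from_trace, hpd_interval, model_from_trace_row
from .likelihood_engine import (LikelihoodContext, PruningEngine, _as_q,
                                branch_transition_matrices,
                                transition_probabilities)
from .treedata_io import TimeTree, TipAreas, Trace, TreeSet, as_tree_set


@dataclass
class DispersalHistory:
    """Full character history: node states + per-branch ordered event lists.

    ``branch_events[node]`` lists events on the branch above ``node`` as
    (time offset from branch start, from_area, to_area), strictly increasing
    in time and chaining consistently from the parent state to the node state.
    """

    tree: TimeTree
    k: int
    node_states: np.ndarray
    branch_events: dict[int, list[tuple[float, int, int]]] = field(
        default_factory=dict)

    def validate(self) -> None:
        tree = self.tree
        for node in range(tree.n_nodes):
            if node == tree.root:
                continue
            events = self.branch_events.get(node, [])
            t = tree.blen[node]
            cur = int(self.node_states[tree.parent[node]])
            last = 0.0
            for (tau, a, b) in events:
                if not last < tau < t:
                    raise ValueError(
                        f"event times on branch {node} must be strictly "
                        f"increasing within (0, {t})")
                if a != cur:
                    raise ValueError(f"event chain broken on branch {node}")
                if a == b:
                    raise ValueError(f"self-transition recorded on branch {node}")
                cur = int(b)
                last = tau
            if cur != int(self.node_states[node]):
                raise ValueError(f"branch {node} does not end in the node state")

    @property
    def total_events(self) -> int:
        return sum(len(v) for v in self.branch_events.values())


@dataclass(frozen=True)
class EventCountMatrix:
    """k x k matrix of dispersal-event counts between ordered area pairs."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if np.any(np.diag(c) != 0):
            raise ValueError("diagonal of an event-count matrix must be zero")
        if np.any(c < 0):
            raise ValueError("event counts must be nonnegative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def unordered(self) -> np.ndarray:
        """Aggregate ordered counts to unordered pairs (upper triangle)."""
        c = self.counts
        return np.triu(c + c.T, k=1)


def count_events_by_pair(history: DispersalHistory) -> EventCountMatrix:
    """Tally i -> j dispersal events across all branches."""
    counts = np.zeros((history.k, history.k), dtype=np.int64)
    for events in history.branch_events.values():
        for (_, a, b) in events:
            counts[a, b] += 1
    return EventCountMatrix(counts)


# ---------------------------------------------------------------------------
# Unconditional (forward) simulation


def simulate_history(tree: TimeTree, model: DispersalModel,
                     rng: np.random.Generator) -> DispersalHistory:
    """Forward-simulate a dispersal history: root state from the root
    frequencies, then Gillespie simulation down every branch."""
    q = build_rate_matrix(model).q
    k = model.k
    exit_rates = -np.diag(q)
    jump_probs = np.where(exit_rates[:, None] > 0, q / np.where(
        exit_rates[:, None] > 0, exit_rates[:, None], 1.0), 0.0)
    np.fill_diagonal(jump_probs, 0.0)

    states = np.full(tree.n_nodes, -1, dtype=np.int64)
    states[tree.root] = rng.choice(k, p=model.root_freqs)
    branch_events: dict[int, list[tuple[float, int, int]]] = {}
    for node in tree.preorder:
        node = int(node)
        if node == tree.root:
            continue
        cur = int(states[tree.parent[node]])
        t_end = tree.blen[node]
        tau = 0.0
        events: list[tuple[float, int, int]] = []
        while True:
            rate = exit_rates[cur]
            if rate <= 0:
                break
            tau += rng.exponential(1.0 / rate)
            if tau >= t_end:
                break
            nxt = int(rng.choice(k, p=jump_probs[cur]))
            events.append((tau, cur, nxt))
            cur = nxt
        states[node] = cur
        if events:
            branch_events[node] = events
    return DispersalHistory(tree=tree, k=k, node_states=states,
                            branch_events=branch_events)


# ---------------------------------------------------------------------------
# Conditional sampling (stochastic mapping)


def sample_node_states(ctx: LikelihoodContext, rng: np.random.Generator,
                       pmats: Optional[np.ndarray] = None,
                       engine: Optional[PruningEngine] = None) -> np.ndarray:
    """Joint draw of all node states from their exact conditional distribution
    given the observed tips (root from its posterior, then preorder)."""
    qm = _as_q(ctx.q)
    if pmats is None:
        pmats = branch_transition_matrices(qm, ctx.tree.blen)
    if engine is None:
        engine = PruningEngine.from_context(ctx)[0]
    part, _ = engine.partials(pmats)
    tree = ctx.tree
    states = np.full(tree.n_nodes, -1, dtype=np.int64)
    root_post = ctx.root_freqs * part[tree.root]
    total = root_post.sum()
    if total <= 0:
        raise ValueError("data have zero likelihood under this model")
    states[tree.root] = rng.choice(len(root_post), p=root_post / total)
    for node in tree.preorder:
        node = int(node)
        if node == tree.root:
            continue
        ps = int(states[tree.parent[node]])
        w = pmats[node][ps] * part[node]
        states[node] = rng.choice(len(w), p=w / w.sum())
    return states


def endpoint_conditioned_history(q: Union[RateMatrix, np.ndarray], t: float,
                                 state_a: int, state_b: int,
                                 rng: np.random.Generator,
                                 p_t: Optional[np.ndarray] = None
                                 ) -> list[tuple[float, int, int]]:
    """Sample a CTMC path on [0, t] from ``state_a`` to ``state_b`` by
    uniformization.

    The dominating rate is ``Lambda = max_i |q_ii|``; the number of candidate
    jumps is drawn from its endpoint-conditioned distribution, jump times are
    uniform order statistics, jump states are sampled backward-consistently
    from powers of the uniformized kernel, and virtual self-jumps are removed.
    """
    qm = _as_q(q)
    k = qm.shape[0]
    a, b = int(state_a), int(state_b)
    lam = float(np.max(-np.diag(qm)))
    if t == 0 or lam == 0:
        if a != b:
            raise ValueError("impossible endpoint pair on a zero-length/ rateless branch")
        return []
    if p_t is None:
        p_t = transition_probabilities(qm, t)
    pab = p_t[a, b]
    if pab <= 0:
        raise ValueError(f"endpoint pair ({a}->{b}) has zero probability at t={t}")
    r = np.eye(k) + qm / lam
    # n | a, b, t: proportional to Poisson(lam t)(n) * R^n[a,b]
    lt = lam * t
    n_cap = int(lt + 12.0 * math.sqrt(lt) + 40)
    u = rng.random()
    pois = math.exp(-lt)
    rpow = [np.eye(k)]
    cum = pois * rpow[0][a, b] / pab
    n = 0
    while cum < u and n < n_cap:
        n += 1
        pois *= lt / n
        rpow.append(rpow[-1] @ r)
        cum += pois * rpow[n][a, b] / pab
    times = np.sort(rng.random(n)) * t
    states = [a]
    for m in range(1, n + 1):
        prev = states[-1]
        w = r[prev] * rpow[n - m][:, b]
        states.append(int(rng.choice(k, p=w / w.sum())))
    events = [(float(times[m - 1]), states[m - 1], states[m])
              for m in range(1, n + 1) if states[m] != states[m - 1]]
    return events


def sample_full_mapping(ctx: LikelihoodContext, rng: np.random.Generator,
                        pmats: Optional[np.ndarray] = None,
                        engine: Optional[PruningEngine] = None
                        ) -> DispersalHistory:
    """One stochastic mapping: node states, then endpoint-conditioned paths."""
    qm = _as_q(ctx.q)
    if pmats is None:
        pmats = branch_transition_matrices(qm, ctx.tree.blen)
    states = sample_node_states(ctx, rng, pmats=pmats, engine=engine)
    tree = ctx.tree
    branch_events: dict[int, list[tuple[float, int, int]]] = {}
    for node in range(tree.n_nodes):
        if node == tree.root:
            continue
        events = endpoint_conditioned_history(
            qm, tree.blen[node], states[tree.parent[node]], states[node],
            rng, p_t=pmats[node])
        if events:
            branch_events[node] = events
    return DispersalHistory(tree=tree, k=qm.shape[0], node_states=states,
                            branch_events=branch_events)


# ---------------------------------------------------------------------------
# Posterior event-count summaries


@dataclass
class EventCountSummary:
    """Posterior summaries of dispersal-event counts between ordered pairs."""

    alphabet_areas: tuple[str, ...]
    mean_counts: np.ndarray           # k x k posterior-mean matrix
    hpd_lower: np.ndarray
    hpd_upper: np.ndarray
    total_samples: np.ndarray         # per-draw total event counts
    probability: float = 0.95

    @property
    def total_mean(self) -> float:
        return float(self.total_samples.mean())

    @property
    def total_hpd(self) -> tuple[float, float]:
        return hpd_interval(self.total_samples, self.probability)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.alphabet_areas)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                rows.append({
                    "from": self.alphabet_areas[i], "to": self.alphabet_areas[j],
                    "mean": self.mean_counts[i, j],
                    "hpd_lower": self.hpd_lower[i, j],
                    "hpd_upper": self.hpd_upper[i, j]})
        return pd.DataFrame(rows)


def posterior_event_counts(trace: Trace, trees, tips: TipAreas,
                           n_draws: int, seed: int,
                           base_model: DispersalModel,
                           probability: float = 0.95) -> EventCountSummary:
    """Posterior distribution of per-pair dispersal-event counts.

    For each of ``n_draws`` posterior draws from the trace, one stochastic
    mapping is sampled on that draw's tree with that draw's parameters and its
    events are tallied by ordered area pair.
    """
    tree_set = as_tree_set(trees)
    rng = np.random.default_rng(seed)
    idx = draws_from_trace(trace, n_draws, rng)
    k = base_model.k
    engines = {i: PruningEngine(t, tips.bind(t), k)
               for i, t in enumerate(tree_set)}
    samples = np.zeros((n_draws, k, k), dtype=np.int64)
    for out_row, row_i in enumerate(idx):
        row = trace.table.iloc[int(row_i)]
        model, ti = model_from_trace_row(row, base_model)
        q = build_rate_matrix(model)
        ctx = LikelihoodContext(tree_set[ti], tips, q, model.root_freqs)
        pmats = branch_transition_matrices(q.q, tree_set[ti].blen)
        hist = sample_full_mapping(ctx, rng, pmats=pmats, engine=engines[ti])
        samples[out_row] = count_events_by_pair(hist).counts
    mean = samples.mean(axis=0)
    lo = np.zeros((k, k))
    hi = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                lo[i, j], hi[i, j] = hpd_interval(samples[:, i, j], probability)
    totals = samples.sum(axis=(1, 2))
    return EventCountSummary(tips.alphabet.areas, mean, lo, hi,
                             totals.astype(float), probability)
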