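"""Seeded synthetic trees and geographic datasets.

Every diagnostic in the package is exercised on generated data: a neutral
coalescent tree provides the time-calibrated scaffold, tip areas are simulated
under the dispersal CTMC itself, and a jittered "posterior sample" of trees
stands in for a tree distribution from a sequence analysis. All generators are
pure functions of their seed.

The default scenario (50 tips, 3 areas, mu = 0.5, symmetric rates) is sized so
that full sweeps — inference, cloning, predictive checks, event counts — run
on a single CPU in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .geomodel import (DispersalModel, GeoAlphabet, ModelState,
                       count_free_rate_parameters, default_alphabet)
from .treedata_io import TimeTree, TipAreas, TreeSet
from .model_fit import simulate_tip_data


@dataclass
class FixtureScenario:
    """Parameters of a synthetic dataset; serializes round-trip to JSON."""

    n_tips: int = 50
    k: int = 3
    mu: float = 0.5
    symmetric: bool = True
    seed: int = 0
    pop_size: float = 1.0
    rel_rates: Optional[tuple[float, ...]] = None
    one_tip_per_area: bool = False

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if self.one_tip_per_area and self.n_tips != self.k:
            raise ValueError("one_tip_per_area requires n_tips == k")
        if self.rel_rates is not None:
            m = count_free_rate_parameters(self.k, self.symmetric)
            self.rel_rates = tuple(float(r) for r in self.rel_rates)
            if len(self.rel_rates) != m:
                raise ValueError(f"rel_rates must have length {m}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureScenario":
        d = json.loads(text)
        if d.get("rel_rates") is not None:
            d["rel_rates"] = tuple(d["rel_rates"])
        return cls(**d)


def simulate_coalescent_tree(n_tips: int, seed: Optional[int] = None,
                             pop_size: float = 1.0,
                             rng: Optional[np.random.Generator] = None) -> TimeTree:
    """Standard neutral (Kingman) coalescent tree.

    With ``j`` active lineages the next merge time is exponential with rate
    ``C(j,2) / pop_size``; a uniformly chosen pair merges. The result is
    ultrametric with tip labels ``t1..tn``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    times = np.zeros(n_nodes)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    labels: list[Optional[str]] = [f"t{i + 1}" if i < n_tips else None
                                   for i in range(n_nodes)]
    active = list(range(n_tips))
    t = 0.0
    nxt = n_tips
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(pop_size / (j * (j - 1) / 2.0))
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = active[int(i1)], active[int(i2)]
        parent[a] = parent[b] = nxt
        children[nxt] = [a, b]
        times[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    blen = np.zeros(n_nodes)
    for i in range(n_nodes):
        if parent[i] >= 0:
            blen[i] = times[parent[i]] - times[i]
    return TimeTree(parent, blen, children, labels)


def make_scenario(scenario: FixtureScenario) -> tuple[TimeTree, TipAreas, ModelState]:
    """Generate (tree, tip areas, true model state) for a scenario.

    With ``one_tip_per_area`` each tip is deterministically assigned its own
    area (n_tips == k), producing the minimal-information design where a
    dataset occupying k areas must have experienced at least k - 1 dispersal
    events; otherwise tip areas are simulated under the dispersal CTMC.
    """
    rng = np.random.default_rng(scenario.seed)
    tree = simulate_coalescent_tree(scenario.n_tips, pop_size=scenario.pop_size,
                                    rng=rng)
    alphabet = default_alphabet(scenario.k)
    m = count_free_rate_parameters(scenario.k, scenario.symmetric)
    rel = np.asarray(scenario.rel_rates, float) if scenario.rel_rates is not None \
        else np.ones(m)
    model = DispersalModel(alphabet, scenario.symmetric, rel, mu=scenario.mu)
    if scenario.one_tip_per_area:
        mapping = {label: alphabet.areas[i]
                   for i, label in enumerate(tree.tip_labels)}
        tips = TipAreas(mapping=mapping, alphabet=alphabet)
    else:
        tips = simulate_tip_data(tree, model, rng=rng)
    truth = ModelState(mu=scenario.mu, rel_rates=rel)
    return tree, tips, truth


def make_tree_posterior_stub(base: TimeTree, n_trees: int, jitter: float,
                             seed: Optional[int] = None,
                             rng: Optional[np.random.Generator] = None) -> TreeSet:
    """Stand-in for a posterior sample of trees: copies of ``base`` whose
    branch lengths are multiplied by iid lognormal(0, jitter) factors
    (jitter = 0 gives identical copies; topology is always preserved)."""
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        if jitter == 0:
            trees.append(base.with_branch_lengths(base.blen.copy()))
        else:
            factors = np.exp(rng.normal(0.0, jitter, size=base.n_nodes))
            factors[base.root] = 1.0
            trees.append(base.with_branch_lengths(base.blen * factors))
    return TreeSet(tuple(trees))
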