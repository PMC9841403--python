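"""Discrete-geographic CTMC model: area alphabet, rate matrix, and priors.

Lineage movement among ``k`` discrete areas is modelled as a continuous-time
Markov chain with instantaneous-rate matrix ``Q``. Off-diagonal ``q_ij`` is the
rate of dispersal from area ``i`` to area ``j``; the matrix is rescaled so that
the expected number of dispersal events per unit tree time at the root
frequencies equals the average dispersal rate ``mu``. Priors on ``mu`` and on
the relative rates are first-class objects (:class:`PriorSpec`) so that the
prior-diagnostic machinery (robust-Bayes sweeps, data cloning) can swap them
freely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


class InvalidAlphabetError(ValueError):
    """Raised when an area alphabet has fewer than two distinct areas."""


class DegenerateMatrixError(ValueError):
    """Raised when all relative dispersal rates are zero."""


class PriorConfigError(ValueError):
    """Raised for unsupported prior family/target combinations or hyperparameters."""


@dataclass(frozen=True)
class GeoAlphabet:
    """Ordered set of distinct area labels."""

    areas: tuple[str, ...]

    def __init__(self, areas: Sequence[str]):
        areas = tuple(str(a) for a in areas)
        if len(areas) < 2:
            raise InvalidAlphabetError(
                f"need at least 2 areas, got {len(areas)}: {areas!r}"
            )
        if len(set(areas)) != len(areas):
            raise InvalidAlphabetError(f"duplicate area labels in {areas!r}")
        object.__setattr__(self, "areas", areas)

    @property
    def k(self) -> int:
        return len(self.areas)

    def index(self, label: str) -> int:
        try:
            return self.areas.index(label)
        except ValueError:
            raise KeyError(f"area {label!r} not in alphabet {self.areas!r}") from None

    def __iter__(self):
        return iter(self.areas)

    def __len__(self) -> int:
        return len(self.areas)


def default_alphabet(k: int) -> GeoAlphabet:
    """Alphabet with labels ``A1..Ak`` (``A``, ``B``, ... for k <= 26)."""
    if k <= 26:
        return GeoAlphabet(tuple(chr(ord("A") + i) for i in range(k)))
    return GeoAlphabet(tuple(f"A{i + 1}" for i in range(k)))


def count_free_rate_parameters(k: int, symmetric: bool) -> int:
    """Number of free pairwise dispersal-rate parameters for ``k`` areas.

    ``k(k-1)`` under the asymmetric model (ordered pairs), ``k(k-1)/2`` under
    the symmetric model (unordered pairs). E.g. an asymmetric model with 5
    areas has 20 such parameters; with 10 areas, 90; with 20 areas, 380.
    """
    k = int(k)
    if k < 2:
        raise InvalidAlphabetError(f"k must be >= 2, got {k}")
    n = k * (k - 1)
    return n // 2 if symmetric else n


def rate_pair_labels(alphabet: GeoAlphabet, symmetric: bool) -> list[str]:
    """Column labels for the relative-rate vector, in storage order.

    Symmetric: unordered pairs (i<j) lexicographic by index, ``rate_A_B``.
    Asymmetric: ordered pairs row-major excluding the diagonal, ``rate_A_B``
    meaning A -> B.
    """
    labels = []
    k = alphabet.k
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if symmetric and j < i:
                continue
            labels.append(f"rate_{alphabet.areas[i]}_{alphabet.areas[j]}")
    return labels


@dataclass
class DispersalModel:
    """Fully parameterized dispersal model (alphabet, rates, mu, root freqs)."""

    alphabet: GeoAlphabet
    symmetric: bool
    rel_rates: np.ndarray
    mu: float
    root_freqs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        k = self.alphabet.k
        self.rel_rates = np.asarray(self.rel_rates, dtype=float)
        expected = count_free_rate_parameters(k, self.symmetric)
        if self.rel_rates.shape != (expected,):
            raise ValueError(
                f"rel_rates must have length {expected} "
                f"({'symmetric' if self.symmetric else 'asymmetric'}, k={k}); "
                f"got shape {self.rel_rates.shape}"
            )
        if np.any(self.rel_rates < 0):
            raise ValueError("rel_rates must be nonnegative")
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.root_freqs is None:
            self.root_freqs = np.full(k, 1.0 / k)
        else:
            self.root_freqs = np.asarray(self.root_freqs, dtype=float)
            if self.root_freqs.shape != (k,) or np.any(self.root_freqs < 0):
                raise ValueError("root_freqs must be a length-k nonnegative vector")
            if abs(self.root_freqs.sum() - 1.0) > 1e-12:
                raise ValueError("root_freqs must sum to 1 within 1e-12")

    @property
    def k(self) -> int:
        return self.alphabet.k


@dataclass(frozen=True)
class RateMatrix:
    """Instantaneous-rate (generator) matrix: rows sum to zero."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValueError("q must be square")
        off = q[~np.eye(q.shape[0], dtype=bool)]
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.max(np.abs(q.sum(axis=1))) > 1e-12 * max(1.0, np.max(np.abs(q))):
            raise ValueError("rows of q must sum to zero")
        object.__setattr__(self, "q", q)

    @property
    def k(self) -> int:
        return self.q.shape[0]


def _fill_relative_matrix(k: int, symmetric: bool, rel_rates: np.ndarray) -> np.ndarray:
    r = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(k):
            if i == j or (symmetric and j < i):
                continue
            r[i, j] = rel_rates[idx]
            if symmetric:
                r[j, i] = rel_rates[idx]
            idx += 1
    return r


def build_rate_matrix(model: DispersalModel) -> RateMatrix:
    """Assemble Q from relative rates and rescale to the average rate ``mu``.

    The normalization convention: ``-sum_i pi_i q_ii == mu`` with ``pi`` the
    root frequencies, so the expected number of dispersal events per unit of
    tree time (at those frequencies) equals ``mu`` and the induced prior mean
    on the total event count is ``mu * T`` for a tree of length ``T``.
    """
    k = model.k
    if not np.any(model.rel_rates > 0):
        raise DegenerateMatrixError("all relative rates are zero")
    r = _fill_relative_matrix(k, model.symmetric, model.rel_rates)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(r, -r.sum(axis=1))
    rate0 = -float(np.dot(model.root_freqs, np.diag(r)))
    q = (model.mu / rate0) * r
    return RateMatrix(q)


# ---------------------------------------------------------------------------
# Priors

PRIOR_FAMILIES = ("ctmc_reference", "exponential", "hierarchical_exponential",
                  "gamma", "fixed")
PRIOR_TARGETS = ("mu", "rel_rates", "hyper")

_SUPPORTED = {
    "mu": set(PRIOR_FAMILIES),
    "rel_rates": {"exponential", "gamma", "fixed"},
    "hyper": {"gamma", "fixed"},
}


@dataclass(frozen=True)
class PriorSpec:
    """Named prior family with hyperparameters, applied to one parameter block.

    Families
    --------
    ``exponential``
        hyperparams: ``rate`` (> 0).
    ``gamma``
        hyperparams: ``shape``, ``rate`` (> 0).
    ``ctmc_reference``
        the BEAST-default reference prior on the overall CTMC rate,
        ``f(mu) ∝ mu^(-1/2) exp(-mu T)`` — a Gamma(1/2, rate=T) density where
        ``T`` is the tree length, supplied as evaluation context.
    ``hierarchical_exponential``
        ``mu | lambda ~ Exponential(lambda)`` with
        ``lambda ~ Gamma(hyper_shape, hyper_rate)``; defaults
        ``hyper_shape=0.5`` and ``hyper_rate=0.5*T``. The marginal on ``mu``
        is Lomax(hyper_shape, hyper_rate).
    ``fixed``
        hyperparams: ``value`` — a point mass (the parameter is not sampled).
    """

    family: str
    target: str = "mu"
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in PRIOR_FAMILIES:
            raise PriorConfigError(f"unknown prior family {self.family!r}")
        if self.target not in PRIOR_TARGETS:
            raise PriorConfigError(f"unknown prior target {self.target!r}")
        if self.family not in _SUPPORTED[self.target]:
            raise PriorConfigError(
                f"family {self.family!r} not supported for target {self.target!r}"
            )
        hp = dict(self.hyperparams)
        object.__setattr__(self, "hyperparams", hp)
        required = {
            "exponential": ("rate",),
            "gamma": ("shape", "rate"),
            "fixed": ("value",),
            "ctmc_reference": (),
            "hierarchical_exponential": (),
        }[self.family]
        for name in required:
            if name not in hp:
                raise PriorConfigError(
                    f"{self.family} prior requires hyperparameter {name!r}"
                )
            if name != "value" and not hp[name] > 0:
                raise PriorConfigError(f"hyperparameter {name!r} must be > 0")
        for name in ("hyper_shape", "hyper_rate"):
            if name in hp and not hp[name] > 0:
                raise PriorConfigError(f"hyperparameter {name!r} must be > 0")

    @classmethod
    def from_dict(cls, d: dict, target: str = "mu") -> "PriorSpec":
        return cls(family=d["family"], target=d.get("target", target),
                   hyperparams=dict(d.get("hyperparams", {})))

    def to_dict(self) -> dict:
        return {"family": self.family, "target": self.target,
                "hyperparams": dict(self.hyperparams)}


def _hier_hyper(spec: PriorSpec, T: Optional[float]) -> tuple[float, float]:
    """Resolve (shape a, rate b) of the Gamma hyperprior on lambda."""
    a = spec.hyperparams.get("hyper_shape", 0.5)
    b = spec.hyperparams.get("hyper_rate")
    if b is None:
        if T is None or not T > 0:
            raise PriorConfigError(
                "hierarchical_exponential needs hyper_rate or a tree length T > 0"
            )
        b = 0.5 * T
    return float(a), float(b)


def log_prior_density(spec: PriorSpec, value: float, T: Optional[float] = None) -> float:
    """Log marginal prior density of ``value`` under ``spec``.

    Returns ``-inf`` outside the support (by contract, not an exception). The
    ``ctmc_reference`` family requires the tree length ``T``; for
    ``hierarchical_exponential`` the analytic marginal (Lomax) is returned.
    """
    v = float(value)
    fam = spec.family
    hp = spec.hyperparams
    if fam == "fixed":
        return 0.0 if v == hp["value"] else -math.inf
    if fam == "exponential":
        if v < 0:
            return -math.inf
        r = hp["rate"]
        return math.log(r) - r * v
    if fam == "gamma":
        if v < 0:
            return -math.inf
        return float(stats.gamma.logpdf(v, hp["shape"], scale=1.0 / hp["rate"]))
    if fam == "ctmc_reference":
        if T is None or not T > 0:
            raise PriorConfigError("ctmc_reference prior requires tree length T > 0")
        if v <= 0:
            return -math.inf
        # Gamma(1/2, rate=T): T^(1/2)/Gamma(1/2) * v^(-1/2) * exp(-T v)
        return 0.5 * math.log(T) - math.lgamma(0.5) - 0.5 * math.log(v) - T * v
    if fam == "hierarchical_exponential":
        if v < 0:
            return -math.inf
        a, b = _hier_hyper(spec, T)
        # Lomax(a, b): a * b^a / (b + v)^(a+1)
        return math.log(a) + a * math.log(b) - (a + 1.0) * math.log(b + v)
    raise PriorConfigError(f"unknown family {fam!r}")  # pragma: no cover


def hierarchical_marginal_cdf(spec: PriorSpec, value: float,
                              T: Optional[float] = None) -> float:
    """Analytic CDF of the marginal prior on mu under the hierarchical family."""
    a, b = _hier_hyper(spec, T)
    v = max(float(value), 0.0)
    return 1.0 - (b / (b + v)) ** a


def sample_prior_value(spec: PriorSpec, rng: np.random.Generator,
                       T: Optional[float] = None,
                       size: Optional[int] = None):
    """Draw from the (marginal) prior of a scalar block."""
    fam = spec.family
    hp = spec.hyperparams
    if fam == "fixed":
        val = hp["value"]
        return val if size is None else np.full(size, val)
    if fam == "exponential":
        return rng.exponential(1.0 / hp["rate"], size=size)
    if fam == "gamma":
        return rng.gamma(hp["shape"], 1.0 / hp["rate"], size=size)
    if fam == "ctmc_reference":
        if T is None or not T > 0:
            raise PriorConfigError("ctmc_reference prior requires tree length T > 0")
        return rng.gamma(0.5, 1.0 / T, size=size)
    if fam == "hierarchical_exponential":
        a, b = _hier_hyper(spec, T)
        lam = rng.gamma(a, 1.0 / b, size=size)
        return rng.exponential(1.0 / lam)
    raise PriorConfigError(f"cannot sample family {fam!r}")


@dataclass
class ModelState:
    """Joint parameter state of the geographic model (the MCMC state vector)."""

    mu: float
    rel_rates: np.ndarray
    hyper_lambda: Optional[float] = None
    tree_index: int = 0

    def __post_init__(self) -> None:
        self.rel_rates = np.asarray(self.rel_rates, dtype=float)
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if self.hyper_lambda is not None and not self.hyper_lambda > 0:
            raise ValueError("hyper_lambda must be > 0")
        if self.tree_index < 0:
            raise ValueError("tree_index must be >= 0")


def sample_from_prior(priors: dict, alphabet: GeoAlphabet,
                      T: Optional[float] = None,
                      seed: Optional[int] = None,
                      symmetric: bool = True,
                      rng: Optional[np.random.Generator] = None,
                      n_trees: int = 1) -> ModelState:
    """Independent joint draw of :class:`ModelState` from the prior.

    ``priors`` maps parameter blocks (``"mu"``, ``"rel_rates"``) to
    :class:`PriorSpec`. Under the hierarchical family, lambda is drawn from its
    Gamma hyperprior and mu from Exponential(lambda), exposing lambda in the
    returned state. Identical ``seed`` gives identical draws.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mu_spec: PriorSpec = priors["mu"]
    hyper_lambda = None
    if mu_spec.family == "hierarchical_exponential":
        a, b = _hier_hyper(mu_spec, T)
        hyper_lambda = float(rng.gamma(a, 1.0 / b))
        mu = float(rng.exponential(1.0 / hyper_lambda))
    else:
        mu = float(sample_prior_value(mu_spec, rng, T=T))
    if mu_spec.family != "fixed":
        mu = max(mu, 1e-300)
    m = count_free_rate_parameters(alphabet.k, symmetric)
    rr_spec: PriorSpec = priors.get(
        "rel_rates", PriorSpec("exponential", "rel_rates", {"rate": 1.0}))
    if rr_spec.family == "fixed":
        val = rr_spec.hyperparams["value"]
        rel = np.full(m, float(val)) if np.isscalar(val) else np.asarray(val, float)
    else:
        rel = np.asarray(sample_prior_value(rr_spec, rng, T=T, size=m), dtype=float)
    tree_index = int(rng.integers(n_trees)) if n_trees > 1 else 0
    return ModelState(mu=mu, rel_rates=rel, hyper_lambda=hyper_lambda,
                      tree_index=tree_index)
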