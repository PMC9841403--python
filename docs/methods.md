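# Methods

## The model

Dispersal of a sampled lineage (typically a pathogen) among `k` discrete
geographic areas is modelled as a homogeneous continuous-time Markov chain
running over a fixed, rooted, time-calibrated phylogeny. The chain is
specified by a `k × k` instantaneous-rate matrix `Q` whose off-diagonal
element `q_ij` is the rate of dispersal from area `i` to area `j`. `Q` is
assembled from nonnegative relative rates — one per unordered pair under the
symmetric model (`k(k−1)/2` parameters) or per ordered pair under the
asymmetric model (`k(k−1)`) — and an overall average dispersal rate `μ`.

**Normalization.** Relative rates are rescaled so that
`−Σ_i π_i q_ii = μ`, with `π` the root frequencies. Under this convention `μ`
is the expected number of dispersal events per unit of tree time, so a tree of
total branch length `T` induces a mean of `μ·T` events a priori. The identity
is exact when `π` is the stationary distribution of `Q` (always true for the
defaults: uniform `π` with symmetric rates); for non-stationary root
frequencies the realized mean drifts slightly as the state distribution
relaxes toward stationarity along the tree.

Root frequencies default to uniform `1/k` and are configurable. Relative
rates are identifiable only up to scale given the normalization; the sampler
draws them as unconstrained positive values and relies on the normalization,
so only their ratios are meaningful.

The data are a single discrete character: the area in which each tip was
sampled. This is the defining statistical difficulty — up to `k(k−1)` rate
parameters confront one observation per tip — and the reason the package
exists: such inferences can be dominated by their priors, and the diagnostics
here measure whether they are.

## Likelihood

The likelihood of the tip areas is computed by Felsenstein pruning with
per-node rescaling. Transition matrices `P(t) = exp(Qt)` come from a dense
eigendecomposition of `Q` (cached and reused across branch lengths and across
`μ` values, since `exp(μ Q₀ t)` shares the eigenvectors of `Q₀`), with a
`scipy.linalg.expm` fallback when the eigenvector matrix has condition number
above 1e8. Entries are clipped to `[0, 1]` and rows renormalized; row sums
are enforced to 1e−10. A brute-force oracle (explicit summation over all
internal-node state assignments, limited to 5 internal nodes) verifies the
pruning implementation in the tests.

The powered likelihood `L^β` is computed as `β · log L`. For integer `β` this
equals the likelihood of `β` literal copies of the character, which is how
data cloning is realized exactly without duplicating data; the engine also
accepts a list of characters so the equivalence itself is testable.

## Priors

Supported families for `μ`:

| family | form | default hyperparameters |
|---|---|---|
| `exponential` | Exp(rate) | — |
| `gamma` | Gamma(shape, rate) | — |
| `ctmc_reference` | ∝ `μ^(−1/2) e^(−μT)` = Gamma(1/2, rate `T`) | `T` = tree length |
| `hierarchical_exponential` | `μ\|λ ~ Exp(λ)`, `λ ~ Gamma(0.5, 0.5·T̄)` | `T̄` = mean tree length |
| `fixed` | point mass | — |

The `ctmc_reference` form is the standard reference prior for an overall CTMC
rate on a tree of length `T`; its marginal mean `0.5/T` anticipates on the
order of half a dispersal event on the whole tree, which is exactly the kind
of hidden informativeness the diagnostics are designed to expose. The
hierarchical family's marginal on `μ` is Lomax(0.5, 0.5·T̄) — heavy-tailed,
hence comparatively uninformative; `λ` is sampled explicitly in the MCMC.
Relative rates default to iid Exponential(mean 1). Units of `μ` (and all rate
hyperparameters) are events per unit of branch-length time.

## MCMC

The sampler is plain Metropolis–Hastings over `(μ, relative rates, λ, tree
index)`. Scalar blocks move by multiplicative scale proposals
`x' = x·exp(tuning·(u−1/2))` with Hastings log-ratio `log(x'/x)`; the tree
index (when a posterior sample of trees is supplied) is redrawn uniformly
every `tree_jump_period` iterations (default 1) and accepted through the full
posterior ratio, which marginalizes the geographic inference over
phylogenetic uncertainty. There is no adaptive tuning: a chain is a pure
function of its seed, and replicate analyses are chains with distinct seeds.
Burn-in is never discarded silently inside `run_chain`; callers (and the
sweep drivers, which default to 10%) discard by fraction explicitly.

Degenerate cases: blocks under a `fixed` prior are never proposed; a block
with zero accepted proposals after 100 attempts triggers a runtime warning.

Diagnostics follow the stated conventions exactly: ESS uses
`N / (1 + 2 Σ ρ̂_t)` with the initial-positive-sequence truncation (lag pairs
summed until the first nonpositive pair; constant series report `N` with a
warning), and the HPD interval is the narrowest window containing
`⌈p·N⌉` sorted samples.

## Prior diagnostics

**Robust Bayes.** `run_robust_bayes` re-runs identical chains under each
named prior configuration and compares the pooled `μ` posteriors through an
HPD overlap coefficient (`|I₁∩I₂| / min(|I₁|,|I₂|)`). Overlap below 0.35
flags prior sensitivity — the threshold is this package's documented choice,
since the comparison is usually described only qualitatively. Cells whose
`μ` ESS falls below 100 are flagged, never dropped.

**Data cloning.** `run_data_cloning` runs one powered chain per clone count
(default schedule `{0, 1, 5, 20}`). As the clone count grows the posterior
must concentrate on the maximum-likelihood estimate; a posterior mean that
moves materially between `β = 1` and `β = 20` indicates a prior that
contributes substantially to the posterior. The per-cell summary reports the
posterior mean, variance, and `β·variance` (which stabilizes once the
Gaussian asymptotics set in). The reference MLE comes from `grid_mle`, a
log-spaced grid search over `μ` iteratively refined to relative width 1e−4,
with a flat-likelihood guard for data with no information about `μ`.

**Induced event-count prior.** `induced_event_count_prior` pushes a prior on
`(μ, rates)` through the tree: each draw simulates one unconditioned history
and counts its events. Because a dataset occupying `m` areas logically
requires at least `m − 1` dispersal events, the report includes the prior
mass below that floor — mass the prior wastes on impossible histories.

## Model fit

**Posterior predictive.** For each posterior draw a replicate dataset is
simulated forward from that draw's parameters (and tree), and a summary
statistic is compared with its observed value. Two default statistics are
provided — the Fitch parsimony score of the geographic character (sensitive
to how much dispersal the model implies) and the multinomial log-likelihood
of the tip-area counts (sensitive to the evenness of the predicted
occupancy); the statistic interface is a plain callable, so user statistics
plug in directly. The upper-tail p-value uses the midpoint tie rule
(`p = (#{sim > obs} + ½·#{sim = obs})/n`), with the two-sided value
`min(1, 2·min(p, 1−p))`; a constant statistic therefore yields `p = 1/2`
and a two-sided value of 1 rather than a spurious extreme.

**Marginal likelihoods.** `run_power_posterior` runs a ladder of powered
chains at `β_j = (j/K)^(1/0.3)` (Beta(0.3, 1) quantiles, `K = 32` by
default, concentrating rungs near the prior where the integrand changes
fastest). The stepping-stone estimator sums log-sum-exp–stabilized ratio
estimates between adjacent rungs using the lower rung's samples; path
sampling integrates the mean log-likelihood over `β` by the trapezoid rule.
Bayes factors are differences of log marginal likelihoods. A quadrature
oracle (`quadrature_lnML_1d`, trapezoid on a 10000-point log-spaced `μ`
grid) provides the ground truth for 1-D problems in the tests.

## Stochastic mapping

Conditional histories are drawn in two stages: node states jointly from their
exact conditional distribution (root from `π ⊙ partial`, then preorder
conditional draws), and each branch path by endpoint-conditioned
uniformization with dominating rate `Λ = max_i |q_ii|` and no inflation
factor. The number of candidate jumps is drawn from its exact
endpoint-conditioned distribution (Poisson terms weighted by powers of the
uniformized kernel, capped at `Λt + 12√(Λt) + 40`, beyond which the residual
mass is below ~1e−12); jump times are uniform order statistics and virtual
self-jumps are discarded. Uniformization was chosen over rejection sampling
because it cannot stall on short branches with unequal endpoint states.
Posterior event counts draw one mapping per posterior draw (standard
practice; configurable by drawing more) and report ordered-pair means and
HPDs, with unordered aggregation available on the count matrix.

## Synthetic data

The generator supplies the study conditions for every test: a Kingman
coalescent tree (merge times exponential with rate `C(j,2)/pop_size`;
ultrametric by construction), tip areas simulated under the dispersal CTMC
itself, and a jittered-branch-length `TreeSet` standing in for a posterior
tree sample (lognormal factors, topology preserved). The default scenario is
50 tips, 3 areas, `μ = 0.5`, symmetric unit rates — small enough that every
sweep in the test suite runs on one CPU in minutes, large enough that the
data visibly pull against the priors. The `one_tip_per_area` option builds
the 10-areas/10-tips minimal-information design whose parsimony floor is 9
events.

What the generator does not emulate: rate heterogeneity across branches or
time, serial (heterochronous) sampling, biased sampling of areas, and any
misspecification between simulating and inference models other than the prior
itself. Passing diagnostics on these fixtures therefore demonstrate
correctness of the machinery and the logic of the diagnostics, not robustness
of real-data analyses to model violations.

## Problem sizes and numerical choices

The test suite and examples use deliberately modest sizes chosen as the
package's own desk-scale defaults: prior-recovery chains of 10^5 iterations
thinned to 5000 samples; cloning on the 50-tip fixture at 14000 iterations
per chain with 5 replicates; marginal-likelihood ladders of 32 stones with
5000 retained samples per rung on a 10-tip toy; 50-replicate
posterior-predictive calibration runs on 20-tip trees; and 20000-draw Monte
Carlo checks of event-count identities. Tolerances follow from the checks
themselves: 1e−12 relative agreement between pruning and exhaustive
summation, 1e−10 row-sum enforcement on transition matrices, KS < 0.03 for
prior recovery at 5000 samples, 0.1 / 0.2 log units for stepping-stone / path
sampling against quadrature, and 3 Monte Carlo standard errors for simulation
identities.

## Known limitations

- Sequential inference only: trees are taken as given (single summary tree or
  posterior sample); geography and phylogeny are never estimated jointly.
- A single homogeneous CTMC character; no BSSVS-style rate-indicator
  selection, no Markov-jump expectation-based counts (sampling-based only),
  no generalized stepping stone with reference distributions.
- The `ctmc_reference` and hierarchical hyperprior forms are documented
  defaults for their named families; other software may parameterize the same
  names differently.
- Relative-rate scale non-identifiability is inherent to the normalized
  parameterization; only rate ratios and `μ` are interpretable.
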