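# geopriorkit

Prior diagnostics for Bayesian discrete-geographic phylodynamic inference.

Discrete phylogeography models the movement of a sampled lineage — typically
a pathogen — among `k` geographic areas as a continuous-time Markov chain
(CTMC) along a time-calibrated phylogeny. The model is specified by a `k × k`
instantaneous-rate matrix `Q` (off-diagonal `q_ij` = rate of dispersal from
area `i` to area `j`, built from pairwise relative rates and rescaled so that
the average dispersal rate is `μ` events per unit tree time). The trouble is
the arithmetic of the data: an asymmetric model with 5 areas has 20 pairwise
rate parameters, with 10 areas 90, with 20 areas 380 — all to be estimated
from a *single* observation per tip (the area where it was sampled). Such
inferences can be dominated by their priors without the analyst noticing.

`geopriorkit` implements the model and, around it, the complete diagnostic
workflow for deciding whether an analysis is prior sensitive and whether the
chosen model fits at all:

- **Robust Bayesian inference** — rerun the same analysis under a sweep of
  candidate priors and compare the marginal posteriors (HPD-overlap flag).
- **Data cloning** — power the likelihood by integer `β` (equivalent to `β`
  copies of the data); as `β` grows the posterior must converge on the
  maximum-likelihood estimate, so the trajectory of the posterior mean across
  `β ∈ {1, 5, 20}` measures the prior's contribution.
- **Induced event-count priors** — translate a prior on `μ` into the number
  of dispersal events it implies on the tree, where minimal knowledge exists
  (data occupying `m` areas require at least `m − 1` events).
- **Posterior-predictive simulation** — absolute model fit via summary
  statistics (Fitch parsimony score and tipwise multinomial log-likelihood by
  default; pluggable).
- **Marginal likelihoods and Bayes factors** — stepping-stone and
  path-sampling estimators over a power-posterior ladder, for relative fit of
  competing (prior) models.
- **Stochastic mapping** — full dispersal histories conditional on the data
  (uniformization), with posterior counts of events between each pair of
  areas.

Everything runs natively at desk scale: a Metropolis–Hastings sampler over
`(μ, relative rates, hyperparameters, tree index)`, a Felsenstein-pruning
likelihood engine, and a seeded synthetic-data module (coalescent trees +
simulated tip areas), so no external programs or datasets are needed.
Phylogenetic uncertainty is handled sequentially: supply a single summary
tree or a posterior sample of trees (Newick lines or NEXUS), and the sampler
marginalizes over the sample.

## Worked example: is the default reference prior informative?

```python
import numpy as np
from geopriorkit import (FixtureScenario, make_scenario, MCMCConfig,
                         PriorSpec, CloningDesign)
from geopriorkit.geomodel import DispersalModel, default_alphabet
from geopriorkit.prior_probes import grid_mle, run_data_cloning

# synthetic study: 50 tips, 3 areas, true mu = 0.5
tree, tips, truth = make_scenario(FixtureScenario(n_tips=50, k=3, mu=0.5, seed=42))

priors = {"mu": PriorSpec("ctmc_reference", "mu"),
          "rel_rates": PriorSpec("fixed", "rel_rates", {"value": 1.0})}
base = DispersalModel(default_alphabet(3), True, np.ones(3), mu=1.0)
print(f"grid MLE of mu = {grid_mle(tips, tree, base):.3f}")

design = CloningDesign(clone_counts=(0, 1, 5, 20), priors=priors, replicates=1)
res = run_data_cloning(design, (tree, tips),
                       MCMCConfig(n_iterations=14000, seed=8, thin=8))
print(res.summary.to_string(index=False))
```

Output:

```
grid MLE of mu = 0.425
 beta  replicate     mean  variance  beta_variance
    0          0 0.060964  0.006883       0.000000
    1          0 0.191458  0.014889       0.014889
    5          0 0.324211  0.010599       0.052993
   20          0 0.394034  0.004419       0.088375
```

Read the table bottom-up. The MLE of `μ` is 0.425, but the plain posterior
mean (`beta = 1`) is 0.191 — less than half of it — because the CTMC-rate
reference prior (the `beta = 0` row: prior mean 0.061) pulls hard toward
slow dispersal. As the data are cloned (`beta = 5`, then `20`) the posterior
mean climbs to 0.394, converging on the MLE exactly as data cloning predicts
for a prior-sensitive analysis. The induced event-count prior makes the
mechanism concrete: under this prior the tree (length `T = 7.85`) carries a
mean of just 0.49 dispersal events, and 88% of the prior mass implies fewer
than 2 events — a strong, and here wrong, prior commitment. Rerunning the
sweep under the hierarchical exponential prior (swap the `"mu"` spec for
`PriorSpec("hierarchical_exponential", "mu")`) gives clone-stable posterior
means, the signature of a diffuse prior.

The same workflow is available from the shell:

```sh
geopriorkit simulate --tips 50 --areas 3 --mu 0.5 --seed 42 --out-prefix fix
geopriorkit clone --trees fix.nwk --tips fix.tips.tsv \
    --prior '{"mu": {"family": "ctmc_reference"}}' \
    --clones 0,1,5,20 --seed 8 --out clone_summary.tsv
geopriorkit ppred --trees fix.nwk --tips fix.tips.tsv --trace trace.log \
    --stat parsimony,multinomial --draws 1000 --seed 1
```

(`infer`, `robust-bayes`, `event-prior`, `marglik`, `counts`, and `convert`
cover the rest; `geopriorkit --help` lists them.)

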