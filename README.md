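# wealthnet

Multilevel social-network analysis of household asset-wealth dynamics in a
rural, surveillance-type population.

Households in many rural southern-African settings function as "stretched"
social groups whose members hold concurrent or sequential memberships in
several households; these shared memberships form a large, sparse
inter-household network nested in administrative regions (*izigodi*).
`wealthnet` asks whether changes in a household's asset wealth are associated
with changes among its network partners — and whether those local
interactions aggregate into rising wealth inequality at the regional level.
Because the underlying surveillance data are licensed, the package ships a
calibrated synthetic-data generator that reproduces the statistical structure
the analysis depends on, so every stage is runnable and testable end to end.

## The model

Outcomes at both levels are modelled jointly with a multilevel autologistic
actor attribute model (ALAAM), an exponential-family distribution over the
binary household outcome vector *y* (wealth-quintile change) and region
outcome vector *Y* (inequality rise ≥ 2 points), conditional on the fixed
multilevel network:

```
Pr(y, Y) = exp( Σ_I θ_I z_I(y, Y; A, B, X, covariates) ) / κ(θ)
```

Each configuration statistic `z_I` counts a local pattern: outcome-weighted
degree within/across regions, outcome-concordant tied pairs (contagion),
region-level connectedness, cross-level interaction, and the micro–macro
link coupling a region's outcome to concordant tied household pairs inside
it. Parameters are estimated by Robbins–Monro stochastic approximation of
the maximum-likelihood score equation `E_θ[z] = z_obs`, with Gibbs sampling
as the inner simulation loop, a Fisher-scoring polish, standard errors from
the inverse simulated-statistic covariance, and convergence/goodness-of-fit
t-ratios. An exact enumeration oracle (≤ 20 nodes) backs the sampler and
estimator with ground truth.

Upstream of the model the package builds the network from membership
episodes (a tie = a shared member 2000–2016), computes the PCA asset-wealth
index and pooled quintiles, the household change outcome, the quintile-Gini
regional inequality score, and baseline (non-network) logistic regressions
with average marginal effects.

## Worked example

```python
from wealthnet import (GeneratorConfig, generate_population, summarise,
                       Effect, EffectSpec, AlaamModel, estimate_rm,
                       gen_outcomes_from_model)

pop = generate_population(GeneratorConfig(n_households=1000, n_regions=10, seed=1))
print(summarise(pop.net, seed=1))

spec = EffectSpec([Effect("density_household", theta=-0.15),
                   Effect("density_region"),
                   Effect("contagion_same_region", theta=0.24)])
state = gen_outcomes_from_model(pop.net, spec, n_burn=300, seed=5)
fit = estimate_rm(AlaamModel(pop.net, spec), state, seed=6)
print(fit.summary().round(3))
```

Output:

```
NetworkSummary(n_nodes=1000, n_edges=861, mean_degree=1.722,
               degree_sd=1.8167872742839213,
               global_clustering=0.19278169014084506,
               mean_path_length=10.448389355742297,
               path_length_sd=3.9855605756637895, n_in_any_component=720,
               largest_component_size=561)
                       theta  std_err  odds_multiplier  conv_t
effect
density_household     -0.174    0.078            0.840  -0.003
density_region        -0.835    0.682            0.434  -0.023
contagion_same_region  0.273    0.073            1.314  -0.016
```

The synthetic network matches the observed topology (mean degree ≈ 1.72,
clustering ≈ 0.19–0.21 across seeds); the fit recovers the same-region
contagion parameter (true 0.24, estimate 0.273 ± 0.073) with all
convergence t-ratios below 0.1. `exp(θ)` is the conditional odds
multiplier: each same-region network partner with a changed outcome
multiplies a household's own odds of change by ≈ 1.3 here (generating value
1.27).

The full study replica runs from the command line:

```
wealthnet --outdir run --seed 1 all     # simulate ... fit-alaam, gof, report
wealthnet --outdir run ladder           # step-wise specification ladder
```

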