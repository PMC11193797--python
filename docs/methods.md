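# Methods

## The multilevel ALAAM

The package models the joint distribution of a binary household outcome
vector *y* (any change in asset-wealth quintile between two survey waves)
and a binary region outcome vector *Y* (rise of at least 2 points in the
regional inequality score) conditional on a fixed multilevel network: the
household–household network A (a tie = a shared member during the
2000–2016 observation window), the household→region affiliation X, and the
derived region–region meta-network B (regions joined by at least one
cross-region household tie). The probability of an outcome configuration is
exponential-family,

    Pr(y, Y) ∝ exp( Σ_I θ_I z_I(y, Y) ),

so each parameter θ_I is the conditional log-odds contribution of one
configuration: flipping one node's outcome changes the log-odds by
θ·Δz_i, where Δz_i is the local change statistic. Because the data are
cross-sectional, "contagion" statistics (outcome-concordant tied pairs)
conflate social influence and social selection; the model measures
association, not causation.

### Implemented statistics

Household level: density (intercept), activity (outcome × degree), closure
(outcome × triangle membership), same-/cross-region degree, same-/cross-
region contagion, a poorest-dyad contagion (both endpoints in the bottom
baseline quintile), and outcome × covariate terms (head sex, pension
eligibility, mortality, household size, baseline quintile, mean shared-tie
years, non-resident count and its square — the quadratic realises the
inverted-U migrant profile inside the model). Region level: density,
within-region tie count, cross-region tie count, meta-network contagion and
outcome × baseline inequality. Cross-level: the interaction Σ_v Y_v·(#
outcome-changed households in v) and the micro–macro link Σ_v Y_v·(#
outcome-concordant same-region tied pairs in v). Closure is the
attribute-weighted triangle count — the simplest closure configuration
consistent with a binary undirected network; sequential (non-overlapping)
shared membership still creates a tie, with zero shared years.

### Estimation

`estimate_rm` solves the method-of-moments condition E_θ[z] = z_obs (the
ML score equation) by three-phase stochastic approximation:

1. **Phase 1** – short Gibbs simulation at the initial θ (densities at the
   logit of observed prevalence, others 0) to estimate a diagonal scaling
   D = Var(z).
2. **Phase 2** – 7 gain-halving sub-phases (a_k = a₀/2^k, a₀ = 0.5) of 40
   iterations × 5 sweeps with updates θ ← θ − a D⁻¹(z_sim − z_obs) and
   Polyak averaging per sub-phase. With D = Var(z) the natural (Newton)
   step is of order 1, which is why a₀ is 0.5 rather than a smaller
   conventional value; smaller gains left visible drift on 1,000-household
   fixtures.
3. **Polish** – a damped Fisher-scoring step Δθ = Cov(z)⁻¹(z_obs − mean z)
   using the full simulated covariance (component cap 0.5), then
4. **Phase 3** – 600 thinned draws for convergence t-ratios
   (mean z_sim − z_obs)/sd(z_sim) (converged iff all |t| < 0.1), standard
   errors from the inverse covariance of simulated statistics, and
   goodness-of-fit t-ratios for all implemented statistics (adequate iff
   |t| < 1.96). Up to 2 phase-2 restarts re-use the phase-3 variance as a
   fresh D. Non-convergence is reported, never raised.

One sweep updates every free node (households then regions, jointly
shuffled) from its full conditional logit θ·Δz_i. All randomness flows
from one root seed through numpy `SeedSequence` spawning, so estimation is
reproducible bit for bit. Missing household outcomes are Gibbs-imputed as
latent by default (a clamp-at-observed mode exists; the two coincide
exactly with an empty mask); when a mask is present, observed and simulated
statistics are both computed on the observed margin, with terms involving
masked nodes excluded explicitly rather than silently zeroed.

On networks with at most 20 total nodes, `exact_loglik` /
`exact_distribution` enumerate all 2^N outcome configurations and serve as
the independent oracle for the sampler (total-variation checks) and the
estimator (comparison with the enumerated-likelihood MLE).

## Wealth index and inequality score

Asset items are standardised on the pooled two-wave household×item matrix
and scored by the first principal component, sign-oriented to correlate
positively with the raw item sum; constant items are dropped. Quintiles
(1 = poorest) are pooled empirical quintiles over household-waves, ties
broken by stable id order, so both waves share one scale. The regional
inequality score is the Gini mean-difference index of within-region
quintile values, G = Σ|x_i − x_j| / (2n²x̄): quintiles rather than raw PCA
scores because the latter can be negative (Gini undefined), and because a
region holding the population quintile mix uniformly scores 4/15 ≈ 0.267,
consistent with the reported baseline average of 0.26. The region outcome
binarises ΔInq ≥ 0.02 (the explicit, reproducible form of the
upper-quartile rule; the μ+0.675σ cut is reported as a diagnostic only).
The household outcome's sensitivity modes (`up`, `down`, `stable`) are a
config switch that partitions households exactly.

## Synthetic-data generator

The generator emulates the study conditions rather than any individual
record. Geography: 23 region centroids on the unit square, households
Gaussian-scattered around them and affiliated to the nearest centroid
(empty regions repaired deterministically). Membership: ~7.83 individuals
per household; each individual holds a primary episode (most spanning the
whole window), and 8.95% acquire a concurrent secondary membership chosen
either two-hop through the existing tie structure (probability 0.315,
closing a triangle) or by region-level distance decay
(weight ∝ size × exp(−20·d)) with a long-tailed (lognormal σ = 0.8)
within-region household attractiveness; 15% of those take a third
membership, tying a three-household clique. Calendar granularity is whole
years — tie definition only needs year-level overlap. These mechanism
parameters were calibrated once against the two observed topology targets
and then frozen; at the full scale (11,834 households) the seed-averaged
topology is mean degree ≈ 1.73 and global clustering ≈ 0.21 (observed:
1.72 and 0.21), with degree SD ≈ 1.8. Average path length is reported but
was deliberately not a calibration target: jointly matching degree,
clustering and path length at fixed size over-constrains a mechanism this
simple.

Non-residency (circular labour migration) has marginal rate 0.28 with a
Beta(0.5, ·) household-level propensity, because migration clusters within
households: independent per-individual draws would give nearly every
household a migrant, contradicting the observed 0–15+ spread of
non-resident counts.

Assets: wave-1 latent wealth is standard normal; wave-2 is an
autocorrelated copy whose correlation is solved (bivariate-normal rectangle
probabilities, bisection) from a latent quintile-stay probability of 0.35,
plus an optional neighbour-quintile contagion shift. Twenty binary items
with loadings 0.6–1.4, spread thresholds and logistic measurement noise
(scale 0.6) are generated with per-household-item noise shared across
waves, so with full persistence the waves are identical. The noise scale
gives Spearman ≈ 0.92 between the PCA score and the true latent wealth;
the shared noise makes observed quintiles stickier than latent ones, which
is why the latent stay probability (0.35) undershoots the observed ~43%
stable share (a majority of households change quintile, matching the
study population).

What the generator does **not** emulate: demography (ages, births, deaths,
fertility), any health process, membership-flow timing within a year,
spatial autocorrelation of wealth, or any dependence of tie formation on
wealth. Passing recovery tests therefore show that the estimator recovers
known parameters under the assumed model on realistic topologies — not
that the substantive findings would replicate on the real data.

## Study designs packaged with the code

Recovery studies (`studies.recovery_study`) generate ~1,000-household,
10-region networks, fix one effect at the log of a reported odds
multiplier, calibrate the two density intercepts to ~50% outcome
prevalence (a short seeded stochastic-approximation loop at the true
parameters), draw one outcome state (300 burn-in sweeps), and re-estimate
a three-parameter model; the median exponentiated estimate over 10
replicates is the headline quantity. The null study repeats this at θ = 0
on 500-household networks. Problem sizes were chosen so a full
acceptance run completes in minutes on one CPU while leaving replicate
noise well inside the reported tolerances.

## Numerical choices and edge cases

- Conditional logits are clamped at |λ| ≤ 35 before exponentiation.
- Degenerate simulated variances flag the effect and report an infinite
  standard error rather than failing.
- Path lengths on components larger than 3,000 nodes are summarised from
  BFS trees rooted at ≥ ⌈10,000/(n−1)⌉ uniformly sampled sources
  (seed-controlled); smaller components are exact.
- Separation in the baseline logistic regressions (relevant with only 23
  regional observations) is detected via non-convergence, runaway
  coefficients or saturated fitted probabilities, and handled by a flagged
  ridge-penalised IRLS refit (penalty 1e-6, intercept unpenalised).
- Quintile ties are broken by stable (wave, household-id) order; regions of
  size one score zero inequality by convention.
- The specification ladder enforces that the micro–macro link enters only
  after the cross-level interaction.

## Known limitations

The tie-formation mechanism is a stand-in: the surveillance concept it
imitates (membership flows driven by kinship, obligation and authority) is
observed only through its network footprint, so the generator is
calibrated to that footprint, not to the process. The estimator uses a
diagonal derivative matrix in phase 2 (full-matrix Newton only in the
polish step); strongly collinear effect sets converge slowly and may
require more sub-phases. The exact oracle is limited to 20 nodes by
enumeration. Cross-sectional contagion estimates remain associational.
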