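# Methods

## Data model and preprocessing

The unit of analysis is a long-format trial table: one row per individual x
trait x trial, with individuals nested in populations nested in regions.
Three assay types are supported, each with its conventional
variance-stabilizing transform:

| trait       | raw measurement                          | transform | notes |
|-------------|------------------------------------------|-----------|-------|
| activity    | grid-transition count per 20-min trial   | sqrt      | integer counts |
| exploration | seconds exploring a novel barrier        | sqrt      | |
| boldness    | latency (s) to re-emerge after a threat  | log10     | 60-min trial; non-emergence coded 3600 s |

Preprocessing applies, in order: (1) removal of trials where the animal never
moved — for the activity and exploration assays only, since a no-movement
boldness trial is a valid (long) latency — and of trials whose recording
failed, for all traits; (2) the transform; (3) z-standardization (sample SD,
n−1) per trait over the full retained dataset with **all groups pooled**.
Per-group standardization would erase exactly the group differences the
models estimate, so pooled constants are the only defensible choice; they are
stored with the table and reapplicable. A boldness latency of exactly 0 is
rejected as physically impossible. The boldness "higher = bolder" inversion
is a display-time sign flip in the reporting layer; models always see
(transformed) latency.

Treating the capped 3600 s boldness latency as an observed value rather than
a right-censored one is a known simplification; with few capped trials it
biases the boldness variance components slightly downward.

## Candidate models

For standardized response y_ij of individual i (group g(i), population
pop(i)):

    y_ij = beta_g + u_i + p_pop(i) + e_ij,
    u_i ~ N(0, sigma_A[g]^2),  e_ij ~ N(0, sigma_W[g]^2),  p_k ~ N(0, sigma_Pop^2)

Groups are regions in the regional analysis (population intercepts included)
and populations in the within-region analysis (no population term; the five
populations are themselves the fixed-effect groups). The four structures are:

1. **null** — sigma_A, sigma_W shared across groups;
2. **among** — group-specific sigma_A only;
3. **within** — group-specific sigma_W only;
4. **both** — both group-specific.

The population-intercept SD is a single shared parameter (one population
random-intercept term, not region-indexed); making it region-specific would
leave 3–4 populations per region to identify each SD.

## Priors

"Weakly informative on the standardized scale" is made concrete as
N(0, 5²) on each group mean and half-Student-t(3, scale 2.5) on every SD —
standard defaults for unit-scale responses; both are configurable
(`Priors`). For the multivariate model each covariance matrix gets the
Huang–Wand (2013) hierarchical inverse-Wishart with ν = 2 and scale 2.5,
chosen because it has *marginally uniform* correlations and half-t margins on
the SDs while keeping the Gibbs conditionals conjugate (Σ | u, a is
inverse-Wishart; the auxiliary a_j are inverse-gamma).

## Sampler

No general-purpose MCMC engine is used; the models are fitted by a dedicated
blocked Gibbs sampler (numpy), exploiting full conjugacy:

* the half-t prior on each SD is realized through its inverse-gamma
  auxiliary-variable representation (sigma² | a ~ InvGamma(ν/2, ν/a),
  a ~ InvGamma(1/2, 1/A²)); the auxiliary is refreshed within each variance
  update, so no auxiliary state persists across sweeps;
* group means, individual intercepts, and population intercepts have normal
  full conditionals (3×3 batched solves in the multivariate case);
* covariance matrices are updated from their inverse-Wishart conditionals.

With only ~2 trials per individual the centered parameterization mixes
notoriously slowly (strong coupling between effects and their scale, and
between group means and effect averages). Two interweaving (ASIS-style)
moves are therefore appended to every sweep:

1. **scale interweave** — re-draw each among-individual (and population) SD
   in the non-centered parameterization, where the SD is a regression
   coefficient with a Student-t prior expressed as a normal scale mixture;
2. **location interweave** — re-draw the group means in the parameterization
   where random effects are centered on their group mean.

Each move is a valid Gibbs step for the same joint posterior; together they
reduce the worst-case split-R̂ at 2 × 1 700 iterations from ≈1.6 to ≈1.01 on
the default regional design. Defaults are 4 chains × 5 000 iterations (1 000
warmup) for univariate fits and 4 × 10 000 for the multivariate model; the
test-suite and acceptance runs use 2 chains × ~2 200 iterations, which the
recovery experiments below show is sufficient at these data sizes. Chains
are seeded from a single `SeedSequence` spawn, so every fit is deterministic
given (data, spec, seed); the synthetic generator similarly derives four
named sub-streams (populations, individuals, residuals, missingness) from
one seed.

Convergence is gated on rank-normalized split-R̂ (computed over every stored
parameter, including latent intercepts) with threshold 1.01; the pipeline
aborts a trait whose fits fail the gate and dumps the diagnostic table.
The implementation agrees with the arviz reference to machine precision
(`method="rank"` and `method="split"`), which the test suite asserts.

## Model comparison

WAIC and PSIS-LOO are computed from the pointwise log-likelihood matrix
(observation-level Gaussian densities conditional on each draw's random
effects). The PSIS smoothing follows the published recipe exactly: tail
fraction min(0.2 S, 3√S), generalized-Pareto fit by the Zhang–Stephens
empirical-Bayes estimator with the weak shape prior, expected-order-statistic
replacement, truncation at the maximum raw weight; tail-shape k is reported
per observation with the 0.5/0.7 thresholds. The primary selection criterion
is elpd_loo (exact ties broken by elpd_waic, then by fewer variance
parameters); the pipeline accepts a `force_model` override — mirroring
analyses that keep one structure across traits for consistency — and logs it.

Observation-level LOO with individual random intercepts and two trials per
individual legitimately produces p_waic > 0.4 and occasional Pareto k > 0.7;
the package warns (as the reference tools do) rather than silencing this.

## Inference

Repeatability is computed draw-wise as R = V_A / (V_A + V_W + V_Pop), with
V_Pop ≡ 0 in the within-region analysis. Δ-quantities are plain draw-wise
posterior differences of variance components (or R) between two groups on
the standardized-response scale; the reporting convention is native minus
invasive (source minus derived). Summaries are medians with central 95%
credible intervals (type-7 quantiles); posterior means are emitted alongside,
medians are primary. A contrast is flagged when both interval endpoints share
a sign; a group is flagged "majority among-individual" when its posterior
median R exceeds 0.5.

The standardized-difference alternative for Δ effect sizes (dividing by a
pooled SD) is deliberately not the default: on unit-variance standardized
responses the raw difference is already an effect size.

## Multivariate (syndrome) model

The three standardized responses share individual effect *vectors*
u_i ~ MVN(0, Σ_g) with an unstructured, region-specific 3×3 Σ_g, population
effect vectors with one shared unstructured covariance, and independent
residuals per trait with region-specific variances (matching the univariate
both-variances structure, which makes the per-trait marginals of the two
models agree — asserted in the tests). Residual covariance across traits is
fixed at zero because the assays are run in separate trials on different
occasions, so trait observations are never paired at the residual level;
consequently within-individual correlations are out of scope. Correlations
are extracted per draw from Σ_g; a pair is a syndrome in a group when its 95%
CI excludes zero.

## Synthetic data generator

The generator is the exact generative mirror of the fitted model: it draws
population effects, correlated individual effect vectors, and trial residuals
on the transformed scale, then inverts the trait transforms (squaring,
rounding activity to integer counts, capping boldness at 3600 s) to produce
raw values, and finally flags a seeded fraction of trials invalid
(no-movement: 2.8% of activity and 3.9% of exploration trials; recording
failure: 3% of all trials in the default configs). Raw-scale marginals are
therefore synthetic conveniences — the generator does not model arena
geometry, assay order, time of day, or any covariate the fitted models omit,
and real raw counts need not be squared Gaussians. What passing recovery
tests demonstrate is that *given data with the assumed hierarchical
structure*, the pipeline recovers the generating variances, correlations and
contrasts at the study's sample sizes — not that the Gaussian assumptions
hold for any particular field dataset (posterior predictive checks exist for
that, comparing observed mean, SD, and per-group SD of individual means with
their replicated distributions).

Default configurations reproduce the study designs: a regional design with
167/118/92/143 individuals in 4/3/3/4 populations (AUS, HAW, LHI, NZ) and a
within-region design with the source population plus four sequentially
established populations (30/31/43/33/36 individuals). Their variance and
mean values are documented placeholders chosen to echo the qualitative
pattern of interest (larger V_A in the native range, larger V_W in invasive
ranges, an activity–exploration syndrome only in the native range); they are
not field estimates. Group mean levels are set high enough on the
transformed scale that clipping at zero is negligible; activity rounding
adds O(10⁻³) variance, negligible against V_W ≈ 0.5.

## Validation experiment sizes

The acceptance suite runs, on one CPU in ~6 minutes total: 20 simulate–fit
cycles of the full regional design for coverage/Δ-bias (and 20 more under
equal variances for contrast calibration), 2 × 20 four-model comparisons at a
two-group design with four-fold variance differences, 10 trivariate fits for
syndrome recovery, exact-LOO and ANOVA-moment oracles, and the formula
identities. Test chains are 2 × ~2 200 iterations; these sizes were chosen as
the smallest at which the moment-level noise of the designs, not the MCMC,
dominates the checks.

## Known limitations

* Gaussian-on-transformed-scale likelihood only; no count or censored-time
  families (the standard field workflow for these assays makes the same
  assumption).
* Boldness censoring at 3600 s treated as observed.
* Shared population-intercept SD across regions (identifiability).
* No covariate adjustment (e.g. body size) and no trial-order effects.
* PosteriorFit persistence writes draws + metadata; reloading a saved fit for
  further computation is not implemented (reports serialize fully).
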