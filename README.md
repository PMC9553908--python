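# behavar

Variance partitioning of repeated behavioral trials: heterogeneous-variance
hierarchical Gaussian models, Bayesian model comparison, repeatability and
variance contrasts, and behavioral syndromes.

## The problem

A recurring question in behavioral ecology — sharpest in studies of invasive
populations — is not whether groups differ in *mean* behavior but whether they
differ in the *structure* of behavioral variation. With repeated assays on
each animal, total phenotypic variance splits into among-individual variance
V_A (consistent personality differences), within-individual variance V_W
(behavioral plasticity across repeated trials), and, in nested designs,
among-population variance V_Pop. The selective-filter hypothesis for
biological invasions predicts that invasive populations show shifted trait
means and *reduced* V_A relative to the native range; comparative work also
asks whether invasion disrupts behavioral syndromes (among-individual
correlations between traits such as activity and exploration).

`behavar` implements that analysis as a tested, reusable pipeline for
long-format trial tables (one row per individual x trait x trial, nested in
populations and regions), together with a synthetic-data generator that
reproduces the nested design of a multi-region skink study (4 regions, 14
populations, 520 individuals, ~2 trials per individual per trait), so every
stage is testable without field data.

## The models

For trial j of individual i in group g (standardized transformed response):

    y_ij = beta_g + u_i + p_pop(i) + e_ij
    u_i  ~ N(0, sigma_A[g]^2),  e_ij ~ N(0, sigma_W[g]^2),  p_k ~ N(0, sigma_Pop^2)

Four candidate random-effect structures are fitted and compared: (1) both
variances shared across groups, (2) group-specific sigma_A, (3) group-specific
sigma_W, (4) both group-specific. Comparison uses WAIC and PSIS-LOO computed
from the pointwise log-likelihood. From the accepted fit the pipeline reports
per-group adjusted short-term repeatability

    R = V_A / (V_A + V_W + V_Pop)

with 95% credible intervals, and posterior contrasts ΔV_A, ΔV_W, ΔR between
groups (flagged when the 95% CI excludes zero). A trivariate model with
group-specific among-individual covariance Σ_g estimates behavioral syndromes
as among-individual correlations.

Fitting is by a blocked Gibbs sampler (conjugate throughout via the
inverse-gamma auxiliary representation of half-t priors, with
interweaved re-parameterization moves for healthy mixing at two trials per
individual); convergence is gated on rank-normalized split-R̂ < 1.01. See
`docs/methods.md` for priors, sampler details, and limitations.

## Worked example

```python
import behavar as bv

table = bv.prepare_model_table(bv.simulate_study(bv.default_regional_config(rng_seed=1)))
fit = bv.fit_univariate(table, bv.ModelSpec(
    trait="exploration", variance_structure="both",
    mcmc=bv.McmcSettings(chains=2, iterations=2200, warmup=600, seed=7)))
fit.check_convergence(threshold=1.02)
report = bv.variance_summary(fit)
row = report.contrast_row("AUS", "NZ", "DV_A")
print(row["median"], (row["lo"], row["hi"]), row["ci_excludes_zero"])
```

Running `python examples/03_repeatability_and_contrasts.py` (which does the
above for every native-invasive pair) prints, for the default synthetic
regional study:

```
  DV_A  AUS - NZ: +0.248 [+0.102, +0.389] *
  DV_W  AUS - NZ: -0.125 [-0.261, +0.007]
  DR    AUS - NZ: +0.313 [+0.125, +0.473] *
```

i.e. the native range (AUS) holds about 0.25 standardized-variance units more
among-individual variation in exploration than the invasive New Zealand range,
and its repeatability is about 0.31 higher — both credible at the 95% level
(starred) — while the within-individual difference is negative (invasives more
plastic) but not credible in this replicate. These recover the pattern built
into the generator's defaults.

The other scripts in `examples/` cover simulation/preprocessing, the
four-model comparison, syndrome estimation, and the end-to-end pipeline; the
same pipeline is scriptable from a shell via the `behavar` CLI
(`simulate`, `preprocess`, `fit`, `compare`, `report`, `run-all`).

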