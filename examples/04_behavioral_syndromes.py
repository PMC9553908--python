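"""Among-individual trait correlations (behavioral syndromes) per region.

Fits the trivariate model in which each individual's three behavioral
intercepts are jointly multivariate normal with a region-specific covariance,
then converts the covariance draws to correlations.  A trait pair is a
"syndrome" in a region when its 95% credible interval excludes zero.
"""

import numpy as np

import behavar as bv

# four regions; an activity-exploration correlation of 0.5 exists only in the
# native range, mirroring the syndrome-disruption question
mk = lambda a, e, b: {"activity": a, "exploration": e, "boldness": b}
corr = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
groups = {
    lab: bv.GroupConfig(
        n_individuals=150, n_populations=2,
        mean=mk(6.0, 10.0, 2.6),
        v_among=mk(0.5, 0.5, 0.10), v_within=mk(0.5, 0.5, 0.10),
        corr_among=corr if lab == "AUS" else None,
    )
    for lab in ("AUS", "HAW", "LHI", "NZ")
}
config = bv.SimConfig(
    traits=("activity", "exploration", "boldness"), groups=groups,
    v_pop={"activity": 0.05, "exploration": 0.05, "boldness": 0.01},
    n_trials=2, rng_seed=4,
)

table = bv.prepare_model_table(bv.simulate_study(config))
spec = bv.MultivariateSpec(
    mcmc=bv.McmcSettings(chains=2, iterations=2200, warmup=600, seed=21),
)
fit = bv.fit_multivariate(table, spec)
report = bv.among_individual_correlations(fit)

print("among-individual correlations, median [95% CI]:")
for _, row in report.frame.iterrows():
    mark = "*" if row["syndrome"] else " "
    print(f"  {row['group']:4s} {row['trait_a']:11s} x {row['trait_b']:11s} "
          f"r = {row['median']:+.3f} [{row['lo']:+.3f}, {row['hi']:+.3f}] {mark}")
print("\nOnly the native range should be starred for activity x exploration: "
      "its individuals that are consistently active are also consistently "
      "exploratory, a coupling absent elsewhere.")
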