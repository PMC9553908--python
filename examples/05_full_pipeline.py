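"""End-to-end pipeline run on a compact synthetic study.

Simulates, preprocesses, fits all four candidate models per trait, gates each
fit on split-Rhat, compares by PSIS-LOO/WAIC, extracts variance and mean
contrast reports, and writes every table plus a checksummed manifest.  The
same entry point drives the within-region (population-level) analysis with
``analysis="within_region_nz"``.
"""

import json
import pathlib

import behavar as bv

mk = lambda a, e: {"activity": a, "exploration": e}
config = bv.SimConfig(
    traits=("activity", "exploration"),
    groups={
        "AUS": bv.GroupConfig(n_individuals=60, n_populations=2,
                              mean=mk(6.0, 9.0), v_among=mk(0.6, 0.8),
                              v_within=mk(0.5, 0.6)),
        "NZ": bv.GroupConfig(n_individuals=60, n_populations=2,
                             mean=mk(6.5, 11.0), v_among=mk(0.3, 0.4),
                             v_within=mk(0.7, 0.9)),
    },
    v_pop=mk(0.05, 0.05), n_trials=2, rng_seed=2,
)

outdir = pathlib.Path("scratch/example_run")
run_config = bv.RunConfig(
    analysis="regional",
    sim_config=config,
    seed=2,
    chains=2,
    iterations=1500,
    warmup=500,
    include_syndromes=False,
    rhat_threshold=1.02,
    output_dir=str(outdir),
)
result = bv.run_regional_analysis(run_config)

print("selected structure per trait:", result.provenance["selected"])
manifest = json.loads((outdir / "manifest.json").read_text())
print("written files:")
for entry in manifest["files"]:
    print("  ", entry["name"])
print("\nEach CSV is a publication-shaped table; provenance.json records the "
      "seed, versions and per-trait model choices so the run can be repeated "
      "byte-identically.")
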