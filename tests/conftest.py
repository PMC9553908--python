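import numpy as np
import pytest

import behavar as bv

# ---------------------------------------------------------------------------
# shared synthetic designs
# ---------------------------------------------------------------------------

REGIONAL_SIZES = {"AUS": (167, 4), "HAW": (118, 3), "LHI": (92, 3), "NZ": (143, 4)}

# generating truths (transformed scale) for the Model-4 recovery experiments:
# distinct per-group among/within variances echoing the native-vs-invasive
# pattern the heterogeneous-variance models are designed to detect
TRUE_VA = {"AUS": 0.7, "HAW": 0.35, "LHI": 0.5, "NZ": 0.25}
TRUE_VW = {"AUS": 0.35, "HAW": 0.6, "LHI": 0.45, "NZ": 0.7}
TRUE_VPOP = 0.08
EQUAL_VA, EQUAL_VW = 0.45, 0.55


def regional_recovery_config(seed: int, equal: bool = False) -> bv.SimConfig:
    """Full regional design (167/118/92/143 individuals, 4/3/3/4 populations,
    2 trials), single continuous trait, known variance truth."""
    groups = {}
    for lab, (n, npop) in REGIONAL_SIZES.items():
        groups[lab] = bv.GroupConfig(
            n_individuals=n,
            n_populations=npop,
            mean={"exploration": 10.0},
            v_among={"exploration": EQUAL_VA if equal else TRUE_VA[lab]},
            v_within={"exploration": EQUAL_VW if equal else TRUE_VW[lab]},
        )
    return bv.SimConfig(
        traits=("exploration",),
        groups=groups,
        v_pop={"exploration": TRUE_VPOP},
        n_trials=2,
        recording_failure_rate=0.03,
        rng_seed=seed,
    )


def two_group_config(seed: int, null: bool = False) -> bv.SimConfig:
    """Compact two-group design for model-selection experiments: four-fold
    among- and within-individual variance differences (or none)."""
    va = (0.45, 0.45) if null else (0.2, 0.8)
    vw = (0.45, 0.45) if null else (0.8, 0.2)
    groups = {
        lab: bv.GroupConfig(
            n_individuals=150,
            n_populations=2,
            mean={"exploration": 10.0},
            v_among={"exploration": vai},
            v_within={"exploration": vwi},
        )
        for lab, vai, vwi in zip(("A", "B"), va, vw)
    }
    return bv.SimConfig(
        traits=("exploration",), groups=groups, v_pop={"exploration": 0.03},
        n_trials=2, rng_seed=seed,
    )


def syndrome_config(seed: int, r: float = 0.5) -> bv.SimConfig:
    """Four-region trivariate design with an activity-exploration
    among-individual correlation in the native region only."""
    mk = lambda a, e, b: {"activity": a, "exploration": e, "boldness": b}
    corr = np.array([[1.0, r, 0.0], [r, 1.0, 0.0], [0.0, 0.0, 1.0]])
    groups = {
        lab: bv.GroupConfig(
            n_individuals=150,
            n_populations=2,
            mean=mk(6.0, 10.0, 2.6),
            v_among=mk(0.5, 0.5, 0.10),
            v_within=mk(0.5, 0.5, 0.10),
            corr_among=corr if lab == "AUS" else None,
        )
        for lab in ("AUS", "HAW", "LHI", "NZ")
    }
    return bv.SimConfig(
        traits=("activity", "exploration", "boldness"),
        groups=groups,
        v_pop={"activity": 0.05, "exploration": 0.05, "boldness": 0.01},
        n_trials=2,
        rng_seed=seed,
    )


def quick_mcmc(seed: int, chains: int = 2, iterations: int = 1500, warmup: int = 500):
    return bv.McmcSettings(chains=chains, iterations=iterations, warmup=warmup, seed=seed)


# ---------------------------------------------------------------------------
# session fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def single_group_table():
    """Balanced single-group dataset (200 individuals x 2 trials), no
    population structure, equal variances on the transformed scale."""
    cfg = bv.SimConfig(
        traits=("exploration",),
        groups={
            "G": bv.GroupConfig(
                n_individuals=200, n_populations=1,
                mean={"exploration": 10.0},
                v_among={"exploration": 0.5},
                v_within={"exploration": 0.5},
            )
        },
        n_trials=2,
        rng_seed=7,
    )
    return bv.prepare_model_table(bv.simulate_dataset(cfg))


@pytest.fixture(scope="session")
def single_group_fit(single_group_table):
    spec = bv.ModelSpec(
        trait="exploration", variance_structure="null",
        include_population_intercept=False, mcmc=quick_mcmc(3),
    )
    return bv.fit_univariate(single_group_table, spec)


@pytest.fixture(scope="session")
def regional_table():
    """Default regional study dataset with missingness injected."""
    return bv.prepare_model_table(bv.simulate_study(bv.default_regional_config(rng_seed=1)))


@pytest.fixture(scope="session")
def regional_fit(regional_table):
    """Model-4 fit of exploration on the default regional dataset."""
    spec = bv.ModelSpec(
        trait="exploration", variance_structure="both",
        mcmc=quick_mcmc(3, iterations=1700),
    )
    return bv.fit_univariate(regional_table, spec)
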