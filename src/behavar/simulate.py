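"""Synthetic repeated-trial behavioral datasets with a nested hierarchical design.

The generator is the generative mirror of the analysis model: each trial value on
the transformed (analysis) scale is

    y = mu_g + pop_effect + individual_effect + residual

with population effects ~ Normal(0, V_Pop[trait]), individual effects drawn per
group from a multivariate normal across traits (diagonal V_A, off-diagonals from
the group's among-individual correlation matrix), and residuals ~ Normal(0,
V_W[group, trait]).  Raw-scale values are obtained by inverting the trait
transform (square for activity/exploration, power of ten for boldness), so the
raw-scale marginals are a synthetic convenience, not an assay model.

Trait conventions
-----------------
activity
    grid-transition count; transformed scale is sqrt(count); raw values are
    rounded to the nearest nonnegative integer.
exploration
    seconds spent exploring a novel barrier; transformed scale is sqrt(seconds).
boldness
    latency (s) to re-emerge after a simulated predator attack within a
    60-minute trial; transformed scale is log10(seconds); raw values are capped
    at 3600 s (non-emergence is recorded as the trial length).

All randomness flows from a single ``rng_seed`` through named
``numpy.random.SeedSequence`` streams (populations, individuals, residuals,
missingness), so each sub-draw is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

TRAITS = ("activity", "exploration", "boldness")

BOLDNESS_MAX_SECONDS = 3600.0

DATASET_COLUMNS = [
    "region",
    "population",
    "individual",
    "trait",
    "trial",
    "value",
    "moved",
    "recorded",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral measurement with its full nesting."""

    individual_id: str
    population_id: str
    region_id: str
    trait: str
    trial_index: int
    raw_value: float
    moved: bool = True
    recorded: bool = True


@dataclass
class GroupConfig:
    """Generative truth for one group (region, or population in the
    within-region analysis)."""

    n_individuals: int
    n_populations: int
    mean: dict[str, float]
    v_among: dict[str, float]
    v_within: dict[str, float]
    corr_among: np.ndarray | None = None  # traits x traits, in config trait order


@dataclass
class SimConfig:
    """Full specification of a synthetic study.

    ``v_pop`` is the population-level variance shared across groups; it may be a
    single float (applied to every trait) or a per-trait mapping, since trait
    scales differ (log10 seconds vs sqrt counts).
    """

    traits: tuple[str, ...]
    groups: dict[str, GroupConfig]
    v_pop: Mapping[str, float] | float = 0.0
    n_trials: int = 2
    invalid_rate_activity: float = 0.028
    invalid_rate_exploration: float = 0.039
    recording_failure_rate: float = 0.0
    rng_seed: int = 0

    def v_pop_for(self, trait: str) -> float:
        if isinstance(self.v_pop, Mapping):
            return float(self.v_pop[trait])
        return float(self.v_pop)

    def validate(self) -> None:
        if not self.traits:
            raise ConfigError("at least one trait is required")
        for t in self.traits:
            if t not in TRAITS:
                raise ConfigError(f"unknown trait {t!r}; expected one of {TRAITS}")
        if len(set(self.traits)) != len(self.traits):
            raise ConfigError("duplicate traits in config")
        if not self.groups:
            raise ConfigError("at least one group is required")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        for rate_name in (
            "invalid_rate_activity",
            "invalid_rate_exploration",
            "recording_failure_rate",
        ):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{rate_name} must be in [0, 1], got {rate}")
        for t in self.traits:
            if self.v_pop_for(t) < 0:
                raise ConfigError(f"V_Pop for {t!r} must be >= 0")
        for label, grp in self.groups.items():
            if grp.n_individuals < 1:
                raise ConfigError(f"group {label!r}: n_individuals must be >= 1")
            if grp.n_populations < 1:
                raise ConfigError(f"group {label!r}: n_populations must be >= 1")
            for t in self.traits:
                for attr in ("mean", "v_among", "v_within"):
                    if t not in getattr(grp, attr):
                        raise ConfigError(f"group {label!r}: missing {attr}[{t!r}]")
                if grp.v_among[t] < 0 or grp.v_within[t] < 0:
                    raise ConfigError(f"group {label!r}: variances must be >= 0")
            if grp.corr_among is not None:
                _validate_correlation(np.asarray(grp.corr_among, float), label, len(self.traits))

    # -- flat key=value serialization ------------------------------------
    def to_flat_dict(self) -> dict[str, str]:
        """Flatten to dotted string keys (documented schema, see to_file)."""
        out: dict[str, str] = {
            "traits": ",".join(self.traits),
            "n_trials": str(self.n_trials),
            "invalid_rate_activity": repr(self.invalid_rate_activity),
            "invalid_rate_exploration": repr(self.invalid_rate_exploration),
            "recording_failure_rate": repr(self.recording_failure_rate),
            "rng_seed": str(self.rng_seed),
            "groups": ",".join(self.groups),
        }
        for t in self.traits:
            out[f"v_pop.{t}"] = repr(self.v_pop_for(t))
        for label, grp in self.groups.items():
            out[f"group.{label}.n_individuals"] = str(grp.n_individuals)
            out[f"group.{label}.n_populations"] = str(grp.n_populations)
            for t in self.traits:
                out[f"group.{label}.mean.{t}"] = repr(float(grp.mean[t]))
                out[f"group.{label}.v_among.{t}"] = repr(float(grp.v_among[t]))
                out[f"group.{label}.v_within.{t}"] = repr(float(grp.v_within[t]))
            if grp.corr_among is not None:
                flat = ",".join(repr(float(v)) for v in np.asarray(grp.corr_among).ravel())
                out[f"group.{label}.corr_among"] = flat
        return out

    @classmethod
    def from_flat_dict(cls, flat: Mapping[str, str]) -> "SimConfig":
        traits = tuple(flat["traits"].split(","))
        labels = flat["groups"].split(",")
        groups: dict[str, GroupConfig] = {}
        for label in labels:
            pref = f"group.{label}."
            corr = None
            if pref + "corr_among" in flat:
                vals = np.array([float(v) for v in flat[pref + "corr_among"].split(",")])
                corr = vals.reshape(len(traits), len(traits))
            groups[label] = GroupConfig(
                n_individuals=int(flat[pref + "n_individuals"]),
                n_populations=int(flat[pref + "n_populations"]),
                mean={t: float(flat[f"{pref}mean.{t}"]) for t in traits},
                v_among={t: float(flat[f"{pref}v_among.{t}"]) for t in traits},
                v_within={t: float(flat[f"{pref}v_within.{t}"]) for t in traits},
                corr_among=corr,
            )
        return cls(
            traits=traits,
            groups=groups,
            v_pop={t: float(flat[f"v_pop.{t}"]) for t in traits},
            n_trials=int(flat["n_trials"]),
            invalid_rate_activity=float(flat["invalid_rate_activity"]),
            invalid_rate_exploration=float(flat["invalid_rate_exploration"]),
            recording_failure_rate=float(flat["recording_failure_rate"]),
            rng_seed=int(flat["rng_seed"]),
        )

    def to_file(self, path) -> None:
        """Write a flat ``key = value`` config file (one pair per line, ``#``
        comments allowed, UTF-8)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# behavar simulation config (flat key = value schema)\n")
            for k, v in self.to_flat_dict().items():
                fh.write(f"{k} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        flat: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                flat[key.strip()] = val.strip()
        return cls.from_flat_dict(flat)


def _validate_correlation(corr: np.ndarray, label: str, n_traits: int) -> None:
    if corr.shape != (n_traits, n_traits):
        raise ConfigError(
            f"group {label!r}: correlation matrix shape {corr.shape} != ({n_traits}, {n_traits})"
        )
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ConfigError(f"group {label!r}: correlation matrix is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ConfigError(f"group {label!r}: correlation matrix diagonal must be 1")
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ConfigError(f"group {label!r}: correlation matrix is not positive semi-definite")


@dataclass
class Dataset:
    """Long-format trial table: one row per individual x trait x trial."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"Dataset frame missing columns: {missing}")
        self.frame = self.frame[DATASET_COLUMNS].reset_index(drop=True)

    def validate(self) -> None:
        """Check nesting consistency and key uniqueness."""
        df = self.frame
        ind_pop = df.groupby("individual")["population"].nunique()
        bad = ind_pop[ind_pop > 1]
        if len(bad):
            raise ValueError(f"individuals mapped to multiple populations: {list(bad.index)[:5]}")
        pop_reg = df.groupby("population")["region"].nunique()
        bad = pop_reg[pop_reg > 1]
        if len(bad):
            raise ValueError(f"populations mapped to multiple regions: {list(bad.index)[:5]}")
        dup = df.duplicated(subset=["individual", "trait", "trial"])
        if dup.any():
            raise ValueError(f"duplicate (individual, trait, trial) keys: {int(dup.sum())} rows")
        act = df[df["trait"] == "activity"]
        if len(act) and not np.allclose(act["value"], np.round(act["value"])):
            raise ValueError("activity raw values must be integers")
        bold = df[df["trait"] == "boldness"]
        if len(bold) and (bold["value"] > BOLDNESS_MAX_SECONDS + 1e-9).any():
            raise ValueError(f"boldness raw values must be <= {BOLDNESS_MAX_SECONDS}")
        if (df["value"] < 0).any():
            raise ValueError("raw values must be nonnegative")

    def design_summary(self) -> dict:
        df = self.frame
        return {
            "n_regions": df["region"].nunique(),
            "n_populations": df["population"].nunique(),
            "n_individuals": df["individual"].nunique(),
            "n_trials_per_trait": {
                t: int(len(df[df["trait"] == t])) for t in df["trait"].unique()
            },
        }

    def invalidation_summary(self) -> pd.DataFrame:
        """Count not-moved and not-recorded flags per trait."""
        df = self.frame
        rows = []
        for trait, sub in df.groupby("trait", sort=True):
            rows.append(
                {
                    "trait": trait,
                    "n_trials": len(sub),
                    "n_not_moved": int((~sub["moved"]).sum()),
                    "n_not_recorded": int((~sub["recorded"]).sum()),
                }
            )
        return pd.DataFrame(rows)

    def iter_records(self) -> Iterator[TrialRecord]:
        for row in self.frame.itertuples(index=False):
            yield TrialRecord(
                individual_id=row.individual,
                population_id=row.population,
                region_id=row.region,
                trait=row.trait,
                trial_index=int(row.trial),
                raw_value=float(row.value),
                moved=bool(row.moved),
                recorded=bool(row.recorded),
            )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        df = pd.read_csv(path)
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset CSV {path}: missing column(s) {missing}")
        for col, wanted in [("trial", int), ("value", float)]:
            try:
                df[col] = df[col].astype(wanted)
            except (TypeError, ValueError) as err:
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                row = int(bad[0]) if len(bad) else -1
                raise ValueError(
                    f"dataset CSV {path}: column {col!r} not parseable at row {row}"
                ) from err
        df["moved"] = df["moved"].astype(bool)
        df["recorded"] = df["recorded"].astype(bool)
        ds = cls(df)
        ds.validate()
        return ds


# ---------------------------------------------------------------------------
# transforms between raw and analysis scales
# ---------------------------------------------------------------------------

def _invert_transform(trait: str, x: np.ndarray) -> np.ndarray:
    """Map transformed-scale draws back to the raw measurement scale."""
    if trait == "activity":
        return np.round(np.clip(x, 0.0, None) ** 2)
    if trait == "exploration":
        return np.clip(x, 0.0, None) ** 2
    if trait == "boldness":
        return np.minimum(10.0 ** x, BOLDNESS_MAX_SECONDS)
    raise ValueError(f"unknown trait {trait!r}")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_STREAMS = ("populations", "individuals", "residuals", "missingness")


def _stream_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def simulate_dataset(config: SimConfig) -> Dataset:
    """Draw a complete trial table from the generative model.

    Identical ``config`` (including ``rng_seed``) gives a byte-identical
    dataset.  All trials come back with ``moved = recorded = True``; use
    :func:`inject_invalid_trials` to add realistic missingness.
    """
    config.validate()
    rngs = _stream_rngs(config.rng_seed)
    traits = list(config.traits)
    n_traits = len(traits)

    rows: list[tuple] = []
    for label in config.groups:  # dict order is deterministic
        grp = config.groups[label]
        pops = [f"{label}_p{k + 1}" for k in range(grp.n_populations)]
        # population effects: independent across traits, variance V_Pop[trait]
        pop_sd = np.array([np.sqrt(config.v_pop_for(t)) for t in traits])
        pop_eff = rngs["populations"].standard_normal((grp.n_populations, n_traits)) * pop_sd

        # individual effects: MVN across traits with diagonal V_A and the
        # group's among-individual correlation matrix
        corr = (
            np.eye(n_traits)
            if grp.corr_among is None
            else np.asarray(grp.corr_among, float)
        )
        sd_a = np.array([np.sqrt(grp.v_among[t]) for t in traits])
        cov = corr * np.outer(sd_a, sd_a)
        # eigendecomposition root: tolerates PSD (zero-variance) matrices
        evals, evecs = np.linalg.eigh(cov)
        root = evecs * np.sqrt(np.clip(evals, 0.0, None))
        ind_eff = rngs["individuals"].standard_normal((grp.n_individuals, n_traits)) @ root.T

        # round-robin assignment of individuals to populations
        pop_of_ind = np.arange(grp.n_individuals) % grp.n_populations
        mu = np.array([grp.mean[t] for t in traits])
        sd_w = np.array([np.sqrt(grp.v_within[t]) for t in traits])

        resid = rngs["residuals"].standard_normal(
            (grp.n_individuals, n_traits, config.n_trials)
        ) * sd_w[None, :, None]
        latent = (
            mu[None, :, None]
            + pop_eff[pop_of_ind][:, :, None]
            + ind_eff[:, :, None]
            + resid
        )
        for i in range(grp.n_individuals):
            ind_id = f"{label}_p{pop_of_ind[i] + 1}_i{i + 1:03d}"
            pop_id = pops[pop_of_ind[i]]
            for ti, trait in enumerate(traits):
                raw = _invert_transform(trait, latent[i, ti])
                for trial in range(config.n_trials):
                    rows.append(
                        (label, pop_id, ind_id, trait, trial + 1, float(raw[trial]), True, True)
                    )

    frame = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    return Dataset(frame)


def inject_invalid_trials(dataset: Dataset, config: SimConfig) -> Dataset:
    """Flag a seeded random fraction of trials as invalid.

    ``moved = False`` on activity trials at ``invalid_rate_activity`` and on
    exploration trials at ``invalid_rate_exploration`` (no-movement assays);
    ``recorded = False`` on all trials at ``recording_failure_rate`` (failed
    video recordings).  Values are untouched.
    """
    config.validate()
    rng = _stream_rngs(config.rng_seed)["missingness"]
    df = dataset.frame.copy()
    n = len(df)
    # one uniform draw per row per mechanism keeps flags independent of row content
    u_moved = rng.random(n)
    u_recorded = rng.random(n)
    act = (df["trait"] == "activity").to_numpy()
    exp_ = (df["trait"] == "exploration").to_numpy()
    moved = df["moved"].to_numpy().copy()
    moved[act & (u_moved < config.invalid_rate_activity)] = False
    moved[exp_ & (u_moved < config.invalid_rate_exploration)] = False
    recorded = df["recorded"].to_numpy() & (u_recorded >= config.recording_failure_rate)
    df["moved"] = moved
    df["recorded"] = recorded
    return Dataset(df)


def simulate_study(config: SimConfig) -> Dataset:
    """Convenience: :func:`simulate_dataset` followed by
    :func:`inject_invalid_trials`."""
    return inject_invalid_trials(simulate_dataset(config), config)


# ---------------------------------------------------------------------------
# default configurations mirroring the study designs
# ---------------------------------------------------------------------------

def default_regional_config(rng_seed: int = 0) -> SimConfig:
    """Four-region design: native Australia plus the Hawaii, Lord Howe Island
    and New Zealand invasive ranges (167/118/92/143 individuals in 4/3/3/4
    populations, two trials per individual per trait).

    The variance and mean values are documented, plausible placeholders chosen
    to echo the qualitative pattern the analysis is designed to detect (larger
    among-individual variance in the native range, larger within-individual
    variance in the invasive ranges, an activity-exploration syndrome only in
    the native range).  They are NOT field estimates.
    """
    corr_native = np.array(
        [
            [1.0, 0.4, 0.0],
            [0.4, 1.0, 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    mk = lambda act, expl, bold: {"activity": act, "exploration": expl, "boldness": bold}
    groups = {
        "AUS": GroupConfig(
            n_individuals=167,
            n_populations=4,
            mean=mk(6.0, 9.0, 2.9),
            v_among=mk(0.8, 1.0, 0.12),
            v_within=mk(0.5, 0.8, 0.08),
            corr_among=corr_native,
        ),
        "HAW": GroupConfig(
            n_individuals=118,
            n_populations=3,
            mean=mk(6.0, 11.0, 2.9),
            v_among=mk(0.6, 0.5, 0.10),
            v_within=mk(0.7, 1.2, 0.12),
        ),
        "LHI": GroupConfig(
            n_individuals=92,
            n_populations=3,
            mean=mk(6.0, 11.0, 3.0),
            v_among=mk(0.6, 0.5, 0.08),
            v_within=mk(0.7, 1.4, 0.18),
        ),
        "NZ": GroupConfig(
            n_individuals=143,
            n_populations=4,
            mean=mk(6.5, 11.0, 2.6),
            v_among=mk(0.4, 0.5, 0.08),
            v_within=mk(0.8, 1.1, 0.15),
        ),
    }
    return SimConfig(
        traits=TRAITS,
        groups=groups,
        v_pop={"activity": 0.10, "exploration": 0.12, "boldness": 0.02},
        n_trials=2,
        recording_failure_rate=0.03,
        rng_seed=rng_seed,
    )


def default_within_region_config(rng_seed: int = 0) -> SimConfig:
    """Five-population design for the within-range expansion analysis: the
    native source population (Tenterfield) plus the four sequentially
    established New Zealand populations.  Populations are the groups, so each
    group holds one population and V_Pop = 0.

    Variance/mean values are plausible placeholders (more recently established
    populations more active and less individually variable), not estimates.
    """
    mk = lambda act, expl, bold: {"activity": act, "exploration": expl, "boldness": bold}
    sizes = {
        "Tenterfield": 30,
        "Auckland": 31,
        "Hamilton": 43,
        "Whangarei": 33,
        "Edgecumbe": 36,
    }
    act_means = {
        "Tenterfield": 5.5,
        "Auckland": 6.0,
        "Hamilton": 6.2,
        "Whangarei": 6.6,
        "Edgecumbe": 6.8,
    }
    v_among_act = {
        "Tenterfield": 0.8,
        "Auckland": 0.6,
        "Hamilton": 0.5,
        "Whangarei": 0.4,
        "Edgecumbe": 0.4,
    }
    groups = {
        label: GroupConfig(
            n_individuals=n,
            n_populations=1,
            mean=mk(act_means[label], 10.0, 2.8),
            v_among=mk(v_among_act[label], 0.7, 0.10),
            v_within=mk(0.6, 1.0, 0.12),
        )
        for label, n in sizes.items()
    }
    return SimConfig(
        traits=TRAITS,
        groups=groups,
        v_pop=0.0,
        n_trials=2,
        recording_failure_rate=0.03,
        rng_seed=rng_seed,
    )
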