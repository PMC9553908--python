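"""End-to-end orchestration of the regional and within-region analyses.

A run takes a long-format trial CSV (or a simulation config in synthetic
mode), prepares the model table, fits the four candidate univariate models
per trait, gates every fit on split-Rhat < 1.01, compares the candidates by
WAIC and PSIS-LOO, extracts variance/repeatability reports and group-mean
contrasts from the selected model (or from a forced model number, mirroring
analyses that keep one structure across traits for consistency), fits the
multivariate syndrome model (regional analysis), and writes every result
table plus a manifest with checksums and full provenance (seeds, versions,
timings).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import MeanContrastReport, VarianceReport, mean_contrasts, variance_summary
from .model_select import ComparisonTable, compare_models
from .preprocess import ModelTable, prepare_model_table
from .simulate import Dataset, SimConfig, simulate_study
from .syndromes import MultivariateSpec, SyndromeReport, among_individual_correlations, fit_multivariate
from .varmodel import ConvergenceError, McmcSettings, ModelSpec, Structure, fit_univariate

log = logging.getLogger("behavar")

_STRUCTURES: tuple[Structure, ...] = ("null", "among", "within", "both")
_NUMBER_TO_STRUCTURE = {i + 1: s for i, s in enumerate(_STRUCTURES)}


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    analysis: str = "regional"  # "regional" | "within_region_nz"
    input_csv: str | None = None          # long-format trial CSV, or
    sim_config: SimConfig | None = None   # synthetic mode
    seed: int = 0
    chains: int = 4
    iterations: int = 5000
    warmup: int = 1000
    mv_iterations: int = 10_000
    force_model: int | None = None        # 1..4, overrides selection
    output_dir: str | None = None
    include_syndromes: bool = True
    rhat_threshold: float = 1.01

    def validate(self) -> None:
        if self.analysis not in ("regional", "within_region_nz"):
            raise ValueError(f"unknown analysis {self.analysis!r}")
        if (self.input_csv is None) == (self.sim_config is None):
            raise ValueError("exactly one of input_csv / sim_config must be given")
        if self.force_model is not None and self.force_model not in _NUMBER_TO_STRUCTURE:
            raise ValueError("force_model must be in 1..4")


@dataclass
class TraitResult:
    trait: str
    comparison: ComparisonTable | None
    variance_report: VarianceReport | None
    mean_report: MeanContrastReport | None
    selected_structure: str | None
    forced: bool
    failed: str | None = None  # diagnostic message if the trait was aborted


@dataclass
class RunResult:
    config: RunConfig
    table: ModelTable
    traits: dict[str, TraitResult]
    syndromes: SyndromeReport | None
    provenance: dict


def read_dataset(path) -> Dataset:
    """Read and validate a long-format trial CSV."""
    return Dataset.from_csv(path)


def _derive_seed(base: int, *salt: str) -> int:
    """Stable sub-seed derivation (documented: blake2 of base + labels)."""
    h = hashlib.blake2b(("/".join([str(base), *salt])).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2 ** 31)


def _fit_trait(table: ModelTable, trait: str, cfg: RunConfig) -> TraitResult:
    include_pop = cfg.analysis == "regional"
    fits = []
    for structure in _STRUCTURES:
        spec = ModelSpec(
            trait=trait,
            variance_structure=structure,
            grouping=table.grouping,
            include_population_intercept=include_pop,
            mcmc=McmcSettings(
                chains=cfg.chains,
                iterations=cfg.iterations,
                warmup=cfg.warmup,
                seed=_derive_seed(cfg.seed, "fit", trait, structure),
            ),
        )
        t0 = time.perf_counter()
        fit = fit_univariate(table, spec)
        log.info("fitted %s / %s in %.1fs (max Rhat %.4f)",
                 trait, structure, time.perf_counter() - t0, fit.max_rhat())
        try:
            fit.check_convergence(cfg.rhat_threshold)
        except ConvergenceError as err:
            diag = fit.rhat_table().sort_values("rhat", ascending=False).head(10)
            log.error("convergence gate failed for %s / %s:\n%s", trait, structure, diag)
            return TraitResult(
                trait=trait, comparison=None, variance_report=None, mean_report=None,
                selected_structure=None, forced=False,
                failed=f"{err} (trait {trait}, structure {structure})",
            )
        fits.append(fit)

    comparison = compare_models(fits)
    if cfg.force_model is not None:
        structure = _NUMBER_TO_STRUCTURE[cfg.force_model]
        forced = structure != [
            f.spec.variance_structure for f in fits if f.spec.label == comparison.selected
        ][0]
        if forced:
            log.warning(
                "force_model=%d overrides selected %s for trait %s",
                cfg.force_model, comparison.selected, trait,
            )
    else:
        structure = next(
            f.spec.variance_structure for f in fits if f.spec.label == comparison.selected
        )
        forced = False
    chosen = next(f for f in fits if f.spec.variance_structure == structure)
    return TraitResult(
        trait=trait,
        comparison=comparison,
        variance_report=variance_summary(chosen),
        mean_report=mean_contrasts(chosen),
        selected_structure=structure,
        forced=forced,
    )


def _load_table(cfg: RunConfig) -> ModelTable:
    if cfg.input_csv is not None:
        dataset = read_dataset(cfg.input_csv)
    else:
        sim = dataclasses.replace(cfg.sim_config, rng_seed=_derive_seed(cfg.seed, "simulate"))
        dataset = simulate_study(sim)
    grouping = "region" if cfg.analysis == "regional" else "population"
    return prepare_model_table(dataset, grouping=grouping)


def _run(cfg: RunConfig) -> RunResult:
    cfg.validate()
    t_start = time.perf_counter()
    table = _load_table(cfg)
    traits = {}
    for trait in table.traits:
        traits[trait] = _fit_trait(table, trait, cfg)

    syndromes = None
    if cfg.include_syndromes and cfg.analysis == "regional" and len(table.traits) >= 2:
        mv_spec = MultivariateSpec(
            grouping=table.grouping,
            include_population_intercept=True,
            mcmc=McmcSettings(
                chains=cfg.chains,
                iterations=cfg.mv_iterations,
                warmup=cfg.warmup,
                seed=_derive_seed(cfg.seed, "multivariate"),
            ),
        )
        mv_fit = fit_multivariate(table, mv_spec)
        mv_fit.check_convergence(cfg.rhat_threshold)
        syndromes = among_individual_correlations(mv_fit)

    provenance = {
        "behavar_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "analysis": cfg.analysis,
        "chains": cfg.chains,
        "iterations": cfg.iterations,
        "warmup": cfg.warmup,
        "force_model": cfg.force_model,
        "runtime_s": time.perf_counter() - t_start,
        "selected": {t: r.selected_structure for t, r in traits.items()},
        "forced": {t: r.forced for t, r in traits.items()},
        "failed": {t: r.failed for t, r in traits.items() if r.failed},
    }
    result = RunResult(
        config=cfg, table=table, traits=traits, syndromes=syndromes, provenance=provenance
    )
    if cfg.output_dir is not None:
        write_results(result, cfg.output_dir)
    return result


def run_regional_analysis(cfg: RunConfig) -> RunResult:
    """Fit Models 1-4 per trait with a region fixed effect and a population
    random intercept, compare, report, and fit the syndrome model."""
    if cfg.analysis != "regional":
        raise ValueError("config analysis must be 'regional'")
    return _run(cfg)


def run_within_region_analysis(cfg: RunConfig) -> RunResult:
    """Same univariate model suite with population as the grouping fixed
    effect and no population random term (repeatability uses V_Pop = 0)."""
    if cfg.analysis != "within_region_nz":
        raise ValueError("config analysis must be 'within_region_nz'")
    return _run(cfg)


def run(cfg: RunConfig) -> RunResult:
    return _run(cfg)


def write_results(result: RunResult, directory) -> list[Path]:
    """Write every result table as CSV/JSON plus ``manifest.json`` listing
    each emitted file with its sha256 checksum."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    for trait, tr in result.traits.items():
        if tr.failed:
            path = d / f"failed_{trait}.json"
            path.write_text(json.dumps({"trait": trait, "reason": tr.failed}, indent=2))
            emit(path)
            continue
        path = d / f"comparison_{trait}.csv"
        tr.comparison.to_csv(path)
        emit(path)
        path = d / f"comparison_{trait}.json"
        tr.comparison.to_json(path)
        emit(path)
        path = d / f"variance_{trait}.csv"
        tr.variance_report.per_group.to_csv(path, index=False)
        emit(path)
        path = d / f"contrasts_{trait}.csv"
        tr.variance_report.to_contrast_csv(path)
        emit(path)
        path = d / f"mean_contrasts_{trait}.csv"
        tr.mean_report.to_csv(path)
        emit(path)
    if result.syndromes is not None:
        path = d / "syndromes.csv"
        result.syndromes.to_csv(path)
        emit(path)
    path = d / "provenance.json"
    path.write_text(json.dumps(result.provenance, indent=2))
    emit(path)

    manifest = {
        "files": [
            {"name": p.name, "sha256": hashlib.sha256(p.read_bytes()).hexdigest()}
            for p in written
        ]
    }
    mpath = d / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    written.append(mpath)
    return written
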