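"""Univariate heterogeneous-variance hierarchical Gaussian models, fitted by
blocked Gibbs sampling.

Model, for observation j of individual i in group g (region or population):

    y_ij = beta_g + u_i + p_pop(i) + e_ij
    u_i   ~ Normal(0, sigma_A[g]^2)   (g-indexed only if structure in {among, both})
    e_ij  ~ Normal(0, sigma_W[g]^2)   (g-indexed only if structure in {within, both})
    p_k   ~ Normal(0, sigma_Pop^2)    (single shared SD, if included)

The four candidate random-effect structures:

    1 "null"   — sigma_A and sigma_W shared across groups
    2 "among"  — group-specific sigma_A only
    3 "within" — group-specific sigma_W only
    4 "both"   — both group-specific

Priors are weakly informative for unit-scale (standardized) responses:
Normal(0, 5^2) on each group mean, half-Student-t(3, scale 2.5) on every SD.
The half-t is realized through its inverse-gamma auxiliary-variable
representation (sigma^2 | a ~ InvGamma(nu/2, nu/a), a ~ InvGamma(1/2, 1/A^2)),
which makes every full conditional conjugate, so the sampler is a plain
blocked Gibbs scheme: (beta | ...), (u | ...), (p | ...), then each variance
and its auxiliary.  Given (data, spec, seed) the fit is deterministic.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .preprocess import ModelTable

Structure = Literal["null", "among", "within", "both"]

_STRUCTURE_NUMBER = {"null": 1, "among": 2, "within": 3, "both": 4}


class ConvergenceError(RuntimeError):
    """Raised when a fit fails the split-Rhat convergence gate."""


@dataclass
class Priors:
    """Weakly-informative defaults for standardized (unit-scale) responses."""

    beta_sd: float = 5.0
    sd_scale: float = 2.5
    sd_df: float = 3.0


@dataclass
class McmcSettings:
    """``iterations`` is the total per chain including warmup (so the default
    4 x 5000 with 1000 warmup keeps 4 x 4000 draws)."""

    chains: int = 4
    iterations: int = 5000
    warmup: int = 1000
    seed: int = 0

    @property
    def kept(self) -> int:
        return self.iterations - self.warmup

    def validate(self) -> None:
        if self.chains < 1:
            raise ValueError("need >= 1 chain")
        if not 0 < self.warmup < self.iterations:
            raise ValueError("need 0 < warmup < iterations")


@dataclass
class ModelSpec:
    """Which variance components vary by group, and how to sample."""

    trait: str
    variance_structure: Structure = "both"
    grouping: str = "region"
    include_population_intercept: bool = True
    priors: Priors = field(default_factory=Priors)
    mcmc: McmcSettings = field(default_factory=McmcSettings)

    @property
    def model_number(self) -> int:
        return _STRUCTURE_NUMBER[self.variance_structure]

    @property
    def label(self) -> str:
        return f"model{self.model_number}_{self.variance_structure}"

    def n_variance_params(self, n_groups: int) -> int:
        n_a = n_groups if self.variance_structure in ("among", "both") else 1
        n_w = n_groups if self.variance_structure in ("within", "both") else 1
        return n_a + n_w + (1 if self.include_population_intercept else 0)

    def validate(self) -> None:
        if self.variance_structure not in _STRUCTURE_NUMBER:
            raise ValueError(
                f"variance_structure must be one of {tuple(_STRUCTURE_NUMBER)}, "
                f"got {self.variance_structure!r}"
            )
        if self.grouping not in ("region", "population"):
            raise ValueError(f"grouping must be 'region' or 'population', got {self.grouping!r}")
        self.mcmc.validate()


# ---------------------------------------------------------------------------
# conjugate building blocks
# ---------------------------------------------------------------------------

def _inv_gamma(rng: np.random.Generator, shape, rate):
    """Draw from InvGamma(shape, rate) elementwise."""
    return np.asarray(rate) / rng.gamma(shape, 1.0, size=np.shape(rate) or None)


def _update_halft_variance(rng, ss, m, sig2, nu, scale):
    """One Gibbs update of sigma^2 under the half-t(nu, scale) prior on sigma,
    given sum of squares ``ss`` over ``m`` zero-mean normal terms.

    The inverse-gamma auxiliary is refreshed within the step
    (a | sigma^2 then sigma^2 | a), so no auxiliary state persists.
    """
    a = _inv_gamma(rng, 0.5 * (nu + 1.0), nu / np.asarray(sig2) + scale ** -2)
    return _inv_gamma(rng, 0.5 * nu + 0.5 * np.asarray(m), nu / a + 0.5 * np.asarray(ss))


# ---------------------------------------------------------------------------
# the Gibbs chain
# ---------------------------------------------------------------------------

def _run_chain(
    y: np.ndarray,
    g_obs: np.ndarray,
    i_obs: np.ndarray,
    k_obs: np.ndarray | None,
    ind_group: np.ndarray,
    pop_group: np.ndarray | None,
    n_groups: int,
    structure: Structure,
    priors: Priors,
    iterations: int,
    warmup: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Run one chain; return kept draws (arrays with leading draw axis)."""
    n = len(y)
    n_ind = len(ind_group)
    include_pop = k_obs is not None
    n_pop = len(pop_group) if include_pop else 0
    G = n_groups
    het_a = structure in ("among", "both")
    het_w = structure in ("within", "both")
    GA = G if het_a else 1
    GW = G if het_w else 1
    gA_ind = ind_group if het_a else np.zeros(n_ind, dtype=np.intp)
    gW_obs = g_obs if het_w else np.zeros(n, dtype=np.intp)
    m_A = np.bincount(gA_ind, minlength=GA).astype(float)
    m_W = np.bincount(gW_obs, minlength=GW).astype(float)
    nu, A = priors.sd_df, priors.sd_scale
    beta_prec0 = priors.beta_sd ** -2

    # overdispersed initialization from data moments
    y_var = float(np.var(y)) if n > 1 else 1.0
    y_var = max(y_var, 1e-3)
    beta = np.zeros(G)
    if n:
        sums = np.bincount(g_obs, y, minlength=G)
        cnts = np.maximum(np.bincount(g_obs, minlength=G), 1)
        beta = sums / cnts
    beta = beta + rng.normal(0.0, 0.5, size=G)
    u = np.zeros(n_ind)
    p = np.zeros(n_pop) if include_pop else None
    sig2_A = np.full(GA, 0.5 * y_var) * np.exp(rng.normal(0.0, 0.5, size=GA))
    sig2_W = np.full(GW, 0.5 * y_var) * np.exp(rng.normal(0.0, 0.5, size=GW))
    sig2_P = np.array([0.25 * y_var]) * np.exp(rng.normal(0.0, 0.5, size=1))
    gA_obs = gA_ind[i_obs] if n else np.empty(0, dtype=np.intp)

    kept = iterations - warmup
    out = {
        "beta": np.empty((kept, G)),
        "u": np.empty((kept, n_ind)),
        "sigma2_A": np.empty((kept, GA)),
        "sigma2_W": np.empty((kept, GW)),
    }
    if include_pop:
        out["p"] = np.empty((kept, n_pop))
        out["sigma2_Pop"] = np.empty((kept, 1))

    for it in range(iterations):
        inv_w = 1.0 / sig2_W[gW_obs] if n else np.empty(0)

        # group means
        r = y - u[i_obs] - (p[k_obs] if include_pop else 0.0) if n else y
        prec = np.bincount(g_obs, inv_w, minlength=G) + beta_prec0
        mean = np.bincount(g_obs, r * inv_w, minlength=G) / prec
        beta = mean + rng.standard_normal(G) / np.sqrt(prec)

        # individual intercepts
        if n_ind:
            r = y - beta[g_obs] - (p[k_obs] if include_pop else 0.0)
            prec = 1.0 / sig2_A[gA_ind] + np.bincount(i_obs, inv_w, minlength=n_ind)
            mean = np.bincount(i_obs, r * inv_w, minlength=n_ind) / prec
            u = mean + rng.standard_normal(n_ind) / np.sqrt(prec)

        # population intercepts
        if include_pop and n_pop:
            r = y - beta[g_obs] - u[i_obs]
            prec = 1.0 / sig2_P[0] + np.bincount(k_obs, inv_w, minlength=n_pop)
            mean = np.bincount(k_obs, r * inv_w, minlength=n_pop) / prec
            p = mean + rng.standard_normal(n_pop) / np.sqrt(prec)

        # variances (half-t prior, auxiliary refreshed within the step)
        ss_A = np.bincount(gA_ind, u ** 2, minlength=GA)
        sig2_A = _update_halft_variance(rng, ss_A, m_A, sig2_A, nu, A)

        resid = y - beta[g_obs] - u[i_obs] - (p[k_obs] if include_pop else 0.0) if n else y
        ss_W = np.bincount(gW_obs, resid ** 2, minlength=GW)
        sig2_W = _update_halft_variance(rng, ss_W, m_W, sig2_W, nu, A)

        if include_pop:
            sig2_P = _update_halft_variance(
                rng, np.array([np.sum(p ** 2)]), np.array([float(n_pop)]), sig2_P, nu, A
            )

        # interweaving (ASIS) rescale: re-draw the effect scales in the
        # non-centered parameterization, where the scale is a regression
        # coefficient with a Student-t(nu, 0, A) prior realized as a normal
        # scale mixture.  This breaks the strong u <-> sigma_A coupling that
        # makes centered Gibbs mix slowly with ~2 trials per individual.
        if n and n_ind:
            inv_w = 1.0 / sig2_W[gW_obs]
            u_tilde = u / np.sqrt(sig2_A[gA_ind])
            tau2 = _inv_gamma(
                rng, 0.5 * (nu + 1.0), 0.5 * (nu * A ** 2 + sig2_A)
            )
            r = y - beta[g_obs] - (p[k_obs] if include_pop else 0.0)
            ut_obs = u_tilde[i_obs]
            prec = np.bincount(gA_obs, ut_obs ** 2 * inv_w, minlength=GA) + 1.0 / tau2
            mean = np.bincount(gA_obs, ut_obs * r * inv_w, minlength=GA) / prec
            s = mean + rng.standard_normal(GA) / np.sqrt(prec)
            sig2_A = s ** 2
            u = s[gA_ind] * u_tilde
        if include_pop and n and n_pop:
            inv_w = 1.0 / sig2_W[gW_obs]
            p_tilde = p / np.sqrt(sig2_P[0])
            tau2 = _inv_gamma(rng, 0.5 * (nu + 1.0), 0.5 * (nu * A ** 2 + sig2_P[0]))
            r = y - beta[g_obs] - u[i_obs]
            pt_obs = p_tilde[k_obs]
            prec = np.sum(pt_obs ** 2 * inv_w) + 1.0 / tau2
            mean = np.sum(pt_obs * r * inv_w) / prec
            s = mean + rng.standard_normal() / np.sqrt(prec)
            sig2_P = np.array([s ** 2])
            p = s * p_tilde

        # location interweave: redraw beta in the parameterization where the
        # random effects are centered on the group mean (c = beta + effect),
        # which decouples beta from the effect averages it drags along in the
        # non-centered sweep.
        if n_ind:
            c = beta[ind_group] + u
            inv_a = 1.0 / sig2_A[gA_ind]
            prec = np.bincount(ind_group, inv_a, minlength=G) + beta_prec0
            mean = np.bincount(ind_group, c * inv_a, minlength=G) / prec
            beta = mean + rng.standard_normal(G) / np.sqrt(prec)
            u = c - beta[ind_group]
        if include_pop and n_pop:
            c = beta[pop_group] + p
            prec = np.bincount(pop_group, minlength=G) / sig2_P[0] + beta_prec0
            mean = np.bincount(pop_group, c, minlength=G) / sig2_P[0] / prec
            beta = mean + rng.standard_normal(G) / np.sqrt(prec)
            p = c - beta[pop_group]

        if it >= warmup:
            s = it - warmup
            out["beta"][s] = beta
            out["u"][s] = u
            out["sigma2_A"][s] = sig2_A
            out["sigma2_W"][s] = sig2_W
            if include_pop:
                out["p"][s] = p
                out["sigma2_Pop"][s] = sig2_P
    return out


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorFit:
    """MCMC draws plus the pointwise log-likelihood matrix.

    ``draws`` arrays are chain-major: shape (chains, kept, ...).  ``loglik``
    is stacked across chains: shape (chains * kept, n_obs), rows ordered
    chain-by-chain.
    """

    draws: dict[str, np.ndarray]
    coords: dict[str, list[str]]
    spec: ModelSpec
    obs_index: pd.DataFrame
    seed: int
    runtime_s: float = 0.0
    _data: dict | None = None
    _loglik: np.ndarray | None = None

    @property
    def loglik(self) -> np.ndarray:
        """Pointwise log-likelihood matrix (draws x observations), computed on
        first access and cached."""
        if self._loglik is None:
            self._loglik = pointwise_loglik(self)
        return self._loglik

    @property
    def n_obs(self) -> int:
        return len(self.obs_index)

    @property
    def n_draws(self) -> int:
        x = next(iter(self.draws.values()))
        return x.shape[0] * x.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains stacked: shape (chains * kept, ...)."""
        x = self.draws[name]
        return x.reshape(-1, *x.shape[2:])

    def sigma2(self, which: str) -> np.ndarray:
        """Variance draws expanded per group: shape (S, n_groups) for 'A' and
        'W' (broadcast when shared), shape (S,) for 'Pop' (zeros if the model
        has no population term)."""
        G = len(self.coords["groups"])
        S = self.n_draws
        if which in ("A", "W"):
            x = self.stacked(f"sigma2_{which}")
            if x.shape[1] == 1:
                x = np.repeat(x, G, axis=1)
            return x
        if which == "Pop":
            if "sigma2_Pop" in self.draws:
                return self.stacked("sigma2_Pop")[:, 0]
            return np.zeros(S)
        raise KeyError(which)

    # -- diagnostics -----------------------------------------------------
    def rhat_table(self, include_latent: bool = True) -> pd.DataFrame:
        rows = []
        for name, x in self.draws.items():
            if not include_latent and name in ("u", "p"):
                continue
            r = split_rhat(x)
            labels = _component_labels(name, x.shape[2], self.coords)
            for lab, val in zip(labels, np.atleast_1d(r)):
                rows.append({"parameter": lab, "rhat": float(val)})
        return pd.DataFrame(rows)

    def max_rhat(self, include_latent: bool = True) -> float:
        table = self.rhat_table(include_latent=include_latent)
        return float(np.nanmax(table["rhat"].to_numpy()))

    def check_convergence(self, threshold: float = 1.01) -> None:
        table = self.rhat_table()
        worst = table.loc[table["rhat"].idxmax()]
        if worst["rhat"] >= threshold:
            raise ConvergenceError(
                f"split-Rhat gate failed: {worst['parameter']} = {worst['rhat']:.4f} "
                f">= {threshold}"
            )

    # -- persistence -----------------------------------------------------
    def save(self, directory) -> None:
        """Documented layout: ``draws.csv`` (one row per chain x draw, one
        column per scalar component) + ``meta.json`` (spec, coords, seed,
        diagnostics)."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cols = {}
        chains, kept = next(iter(self.draws.values())).shape[:2]
        for name, x in self.draws.items():
            labels = _component_labels(name, x.shape[2], self.coords)
            flat = x.reshape(chains * kept, x.shape[2])
            for ci, lab in enumerate(labels):
                cols[lab] = flat[:, ci]
        frame = pd.DataFrame(cols)
        frame.insert(0, "chain", np.repeat(np.arange(chains), kept))
        frame.insert(1, "draw", np.tile(np.arange(kept), chains))
        frame.to_csv(d / "draws.csv", index=False)
        meta = {
            "trait": self.spec.trait,
            "variance_structure": self.spec.variance_structure,
            "grouping": self.spec.grouping,
            "include_population_intercept": self.spec.include_population_intercept,
            "mcmc": {
                "chains": chains,
                "kept": kept,
                "warmup": self.spec.mcmc.warmup,
                "seed": self.seed,
            },
            "coords": self.coords,
            "max_rhat": self.max_rhat(),
            "runtime_s": self.runtime_s,
        }
        with open(d / "meta.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)


def _component_labels(name: str, width: int, coords: dict) -> list[str]:
    axis = {
        "beta": "groups",
        "sigma2_A": "groups",
        "sigma2_W": "groups",
        "u": "individuals",
        "p": "populations",
    }.get(name)
    if name == "sigma2_Pop" or width == 1 and name.startswith("sigma2"):
        return [name]
    labels = coords.get(axis, [str(i) for i in range(width)])
    if len(labels) != width:  # shared variance stored with width 1
        return [name]
    return [f"{name}[{lab}]" for lab in labels]


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _encode(values: np.ndarray) -> tuple[np.ndarray, list]:
    cats = sorted(pd.unique(values))
    lookup = {v: i for i, v in enumerate(cats)}
    return np.array([lookup[v] for v in values], dtype=np.intp), cats


def fit_univariate(table: ModelTable, spec: ModelSpec) -> PosteriorFit:
    """Fit one candidate model to one trait by blocked Gibbs sampling."""
    spec.validate()
    sub = table.for_trait(spec.trait)
    y = sub["y"].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")

    g_obs, groups = _encode(sub["group"].to_numpy())
    i_obs, individuals = _encode(sub["individual"].to_numpy())
    # group of each individual (unique by nesting)
    ind_group = np.zeros(len(individuals), dtype=np.intp)
    ind_group[i_obs] = g_obs
    per_group = np.bincount(ind_group, minlength=len(groups))
    for g, cnt in enumerate(per_group):
        if cnt == 1:
            warnings.warn(
                f"group {groups[g]!r} has a single individual; its among-individual "
                "variance is weakly identified",
                stacklevel=2,
            )

    if spec.include_population_intercept:
        k_obs, populations = _encode(sub["population"].to_numpy())
        pop_group = np.zeros(len(populations), dtype=np.intp)
        pop_group[k_obs] = g_obs
    else:
        k_obs, populations, pop_group = None, [], None

    t0 = time.perf_counter()
    seeds = np.random.SeedSequence(spec.mcmc.seed).spawn(spec.mcmc.chains)
    chains = [
        _run_chain(
            y,
            g_obs,
            i_obs,
            k_obs,
            ind_group,
            pop_group,
            len(groups),
            spec.variance_structure,
            spec.priors,
            spec.mcmc.iterations,
            spec.mcmc.warmup,
            np.random.default_rng(s),
        )
        for s in seeds
    ]
    draws = {name: np.stack([c[name] for c in chains]) for name in chains[0]}
    fit = PosteriorFit(
        draws=draws,
        coords={
            "groups": list(groups),
            "individuals": list(individuals),
            "populations": list(populations),
        },
        spec=spec,
        obs_index=sub[["group", "population", "individual", "trial"]].copy(),
        seed=spec.mcmc.seed,
        _data={"y": y, "g_obs": g_obs, "i_obs": i_obs, "k_obs": k_obs},
    )
    fit.runtime_s = time.perf_counter() - t0
    return fit


def pointwise_loglik(fit: PosteriorFit, table: ModelTable | None = None) -> np.ndarray:
    """Observation-level Gaussian log-density per posterior draw, conditioning
    on that draw's random-effect values: entry (s, j) = log N(y_j | mu_sj,
    sigma_W[s, g(j)]^2)."""
    data = fit._data
    if data is None:
        raise ValueError("fit carries no data arrays; cannot rebuild the likelihood")
    if table is not None:
        sub = table.for_trait(fit.spec.trait)
        if len(sub) != len(data["y"]) or not np.allclose(sub["y"].to_numpy(float), data["y"]):
            raise ValueError("table does not match the observations this fit was trained on")
    y, g_obs, i_obs, k_obs = data["y"], data["g_obs"], data["i_obs"], data["k_obs"]
    beta = fit.stacked("beta")
    u = fit.stacked("u")
    mu = beta[:, g_obs] + u[:, i_obs]
    if k_obs is not None:
        mu += fit.stacked("p")[:, k_obs]
    sig2 = fit.sigma2("W")[:, g_obs]
    return -0.5 * (np.log(2.0 * np.pi * sig2) + (y[None, :] - mu) ** 2 / sig2)


# ---------------------------------------------------------------------------
# split-Rhat
# ---------------------------------------------------------------------------

def split_rhat(x: np.ndarray, rank_normalize: bool = True) -> np.ndarray | float:
    """Rank-normalized split-chain potential scale reduction factor.

    ``x`` has shape (chains, draws) or (chains, draws, K); returns a float or
    a length-K array.  Chains are split in half; values are replaced by normal
    scores of their pooled ranks (the rank-normalized "bulk" variant), then
    the classical between/within ratio sqrt(((n-1)/n W + B/n) / W) is taken
    with n the per-split length.  Constant draws give NaN.
    """
    x = np.asarray(x, float)
    scalar = x.ndim == 2
    if scalar:
        x = x[:, :, None]
    C, N, K = x.shape
    if C < 2 or N < 4:
        raise ValueError("split-Rhat needs >= 2 chains and >= 4 draws per chain")
    n = N // 2
    halves = np.concatenate([x[:, :n], x[:, N - n :]], axis=0)  # (2C, n, K)
    if rank_normalize:
        flat = halves.reshape(2 * C * n, K)
        ranks = rankdata(flat, axis=0, method="average")
        z = ndtri((ranks - 0.375) / (2 * C * n + 0.25))
        halves = z.reshape(2 * C, n, K)
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    W = variances.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(((n - 1) / n * W + B / n) / W)
    out = np.where(W > 0, out, np.nan)
    return float(out[0]) if scalar else out


def rhat(fit: PosteriorFit, parameter: str) -> float:
    """Split-Rhat for a named parameter, e.g. ``"beta[AUS]"``, ``"sigma2_A"``
    (shared), ``"sigma2_W[NZ]"``."""
    name, _, rest = parameter.partition("[")
    x = fit.draws[name]
    if rest:
        label = rest.rstrip("]")
        labels = _component_labels(name, x.shape[2], fit.coords)
        try:
            idx = labels.index(parameter)
        except ValueError as err:
            raise KeyError(f"unknown parameter {parameter!r}") from err
        return float(split_rhat(x[:, :, idx]))
    if x.shape[2] != 1:
        raise KeyError(f"{name!r} has {x.shape[2]} components; give an index like {name}[label]")
    return float(split_rhat(x[:, :, 0]))


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

def posterior_predictive_check(
    fit: PosteriorFit,
    n_rep: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate replicate datasets from posterior draws and compare test
    statistics (overall mean, overall SD, per-group SD of individual means)
    with the observed data.

    Returns one row per statistic with the observed value, the tail
    probability P(T_rep >= T_obs), and an ``adequate`` flag for probabilities
    inside [0.05, 0.95].
    """
    data = fit._data
    if data is None:
        raise ValueError("fit carries no data arrays")
    y, g_obs, i_obs, k_obs = data["y"], data["g_obs"], data["i_obs"], data["k_obs"]
    S = fit.n_draws
    rng = np.random.default_rng(
        np.random.SeedSequence(fit.seed if seed is None else seed).spawn(1)[0]
    )
    take = rng.choice(S, size=min(n_rep, S), replace=False)
    beta = fit.stacked("beta")[take]
    u = fit.stacked("u")[take]
    mu = beta[:, g_obs] + u[:, i_obs]
    if k_obs is not None:
        mu += fit.stacked("p")[take][:, k_obs]
    sig = np.sqrt(fit.sigma2("W")[take][:, g_obs])
    y_rep = mu + sig * rng.standard_normal(mu.shape)

    groups = fit.coords["groups"]
    n_ind = len(fit.coords["individuals"])
    ind_group = np.zeros(n_ind, dtype=np.intp)
    ind_group[i_obs] = g_obs
    counts = np.bincount(i_obs, minlength=n_ind).astype(float)

    def stats(vals: np.ndarray) -> dict[str, float]:
        ind_means = np.bincount(i_obs, vals, minlength=n_ind) / counts
        out = {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1))}
        for g, lab in enumerate(groups):
            sel = ind_means[ind_group == g]
            out[f"sd_ind_means[{lab}]"] = float(np.std(sel, ddof=1)) if len(sel) > 1 else np.nan
        return out

    observed = stats(y)
    rep = [stats(y_rep[s]) for s in range(y_rep.shape[0])]
    rows = []
    for key, obs_val in observed.items():
        rep_vals = np.array([r[key] for r in rep])
        p = float(np.mean(rep_vals >= obs_val))
        rows.append(
            {
                "statistic": key,
                "observed": obs_val,
                "tail_prob": p,
                "adequate": bool(0.05 <= p <= 0.95),
            }
        )
    return pd.DataFrame(rows)
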