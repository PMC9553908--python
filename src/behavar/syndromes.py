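"""Trivariate hierarchical model with group-varying among-individual
covariance, for estimating behavioral syndromes (among-individual trait
correlations).

Each standardized response t of individual i in group g:

    y_ijt = beta_gt + u_it + p_pop(i),t + e_ijt

with individual effect vectors u_i ~ MVN(0, Sigma_g) (unstructured T x T
covariance per group), population effect vectors p_k ~ MVN(0, Sigma_Pop)
(one shared unstructured covariance), and independent residuals e_ijt ~
Normal(0, sigma_W[g, t]^2).  Residual covariance across traits is fixed at
zero: the assays are run in separate trials on different occasions, so trait
observations are never paired at the residual level.

Priors: Normal(0, 5^2) on each mean; half-t(3, 2.5) on residual SDs; on each
covariance matrix the Huang-Wand (2013) hierarchical inverse-Wishart with
nu = 2, which gives marginally uniform correlations and half-t(2, scale A)
margins on the SDs while keeping every Gibbs conditional conjugate
(Sigma | u, a ~ InvWishart; a_j | Sigma ~ InvGamma).

The among-individual correlation between activity and exploration is the
"behavioral syndrome" of interest; a pair is flagged as a syndrome in a group
when its 95% credible interval excludes zero.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .inference import summarize_draws
from .preprocess import ModelTable
from .varmodel import (
    ConvergenceError,
    McmcSettings,
    _inv_gamma,
    _update_halft_variance,
    split_rhat,
)

TRAIT_ORDER = ("activity", "exploration", "boldness")


@dataclass
class MultivariatePriors:
    beta_sd: float = 5.0
    resid_sd_scale: float = 2.5
    resid_sd_df: float = 3.0
    cov_nu: float = 2.0       # Huang-Wand nu: 2 -> marginally uniform correlations
    cov_sd_scale: float = 2.5


@dataclass
class MultivariateSpec:
    grouping: str = "region"
    include_population_intercept: bool = True
    priors: MultivariatePriors = field(default_factory=MultivariatePriors)
    mcmc: McmcSettings = field(default_factory=lambda: McmcSettings(iterations=10_000))

    def validate(self) -> None:
        if self.grouping not in ("region", "population"):
            raise ValueError(f"grouping must be 'region' or 'population', got {self.grouping!r}")
        self.mcmc.validate()


@dataclass
class MultivariateFit:
    """Posterior draws of the trivariate model; arrays are chain-major."""

    draws: dict[str, np.ndarray]
    coords: dict[str, list[str]]
    spec: MultivariateSpec
    traits: list[str]
    obs_index: pd.DataFrame
    seed: int
    runtime_s: float = 0.0
    _data: dict | None = None

    def stacked(self, name: str) -> np.ndarray:
        x = self.draws[name]
        return x.reshape(-1, *x.shape[2:])

    def among_variance(self, trait: str) -> np.ndarray:
        """Per-group among-individual variance draws for one trait: (S, G)."""
        t = self.traits.index(trait)
        return self.stacked("Sigma")[:, :, t, t]

    def pointwise_loglik(self) -> np.ndarray:
        """(draws x observations) Gaussian log-density matrix, columns in
        ``obs_index`` row order (trait blocks concatenated)."""
        if self._data is None:
            raise ValueError("fit carries no data arrays")
        beta = self.stacked("beta")
        u = self.stacked("u")
        p = self.stacked("p") if "p" in self.draws else None
        sig2w = self.stacked("sigma2_W")
        blocks = []
        for t, d in enumerate(self._data["per_trait"]):
            mu = beta[:, d["g_obs"], t] + u[:, d["i_obs"], t]
            if p is not None:
                mu += p[:, d["k_obs"], t]
            s2 = sig2w[:, d["g_obs"], t]
            blocks.append(
                -0.5 * (np.log(2.0 * np.pi * s2) + (d["y"][None, :] - mu) ** 2 / s2)
            )
        return np.concatenate(blocks, axis=1)

    def rhat_table(self) -> pd.DataFrame:
        rows = []
        for name in ("beta", "Sigma", "Sigma_Pop", "sigma2_W"):
            if name not in self.draws:
                continue
            x = self.draws[name]
            flat = x.reshape(x.shape[0], x.shape[1], -1)
            r = np.atleast_1d(split_rhat(flat))
            for i, val in enumerate(r):
                rows.append({"parameter": f"{name}[{i}]", "rhat": float(val)})
        return pd.DataFrame(rows)

    def max_rhat(self) -> float:
        return float(np.nanmax(self.rhat_table()["rhat"].to_numpy()))

    def check_convergence(self, threshold: float = 1.01) -> None:
        if self.max_rhat() >= threshold:
            raise ConvergenceError(
                f"multivariate fit failed the split-Rhat gate (max = {self.max_rhat():.4f})"
            )


def _prepare(table: ModelTable):
    traits = [t for t in TRAIT_ORDER if t in table.traits]
    if len(traits) < 2:
        raise ValueError("multivariate model needs >= 2 traits")
    frames = {t: table.for_trait(t) for t in traits}
    individuals = sorted(set().union(*[set(f["individual"]) for f in frames.values()]))
    ind_lookup = {v: i for i, v in enumerate(individuals)}
    groups = sorted(set().union(*[set(f["group"]) for f in frames.values()]))
    grp_lookup = {v: i for i, v in enumerate(groups)}
    populations = sorted(set().union(*[set(f["population"]) for f in frames.values()]))
    pop_lookup = {v: i for i, v in enumerate(populations)}

    data = {"traits": traits, "groups": groups, "individuals": individuals,
            "populations": populations}
    ind_group = np.full(len(individuals), -1, dtype=np.intp)
    pop_group = np.full(len(populations), -1, dtype=np.intp)
    per_trait = []
    for t in traits:
        f = frames[t]
        i_obs = np.array([ind_lookup[v] for v in f["individual"]], dtype=np.intp)
        g_obs = np.array([grp_lookup[v] for v in f["group"]], dtype=np.intp)
        k_obs = np.array([pop_lookup[v] for v in f["population"]], dtype=np.intp)
        ind_group[i_obs] = g_obs
        pop_group[k_obs] = g_obs
        per_trait.append(
            {"y": f["y"].to_numpy(float), "i_obs": i_obs, "g_obs": g_obs, "k_obs": k_obs}
        )
    if (ind_group < 0).any():
        raise ValueError("individual present in zero traits")  # unreachable from a table
    data.update(ind_group=ind_group, pop_group=pop_group, per_trait=per_trait)
    obs_index = pd.concat(
        [frames[t][["group", "population", "individual", "trait", "trial"]] for t in traits],
        ignore_index=True,
    )
    return data, obs_index


def _run_mv_chain(data, spec: MultivariateSpec, rng: np.random.Generator):
    traits = data["traits"]
    T = len(traits)
    G = len(data["groups"])
    I = len(data["individuals"])
    P = len(data["populations"])
    include_pop = spec.include_population_intercept
    pr = spec.priors
    nu_c, A_c = pr.cov_nu, pr.cov_sd_scale
    nu_r, A_r = pr.resid_sd_df, pr.resid_sd_scale
    per = data["per_trait"]
    ind_group = data["ind_group"]

    n_it = np.zeros((I, T))
    n_gt = np.zeros((G, T))
    for t in range(T):
        n_it[:, t] = np.bincount(per[t]["i_obs"], minlength=I)
        n_gt[:, t] = np.bincount(per[t]["g_obs"], minlength=G)

    # initialization
    beta = np.zeros((G, T))
    for t in range(T):
        sums = np.bincount(per[t]["g_obs"], per[t]["y"], minlength=G)
        beta[:, t] = sums / np.maximum(n_gt[:, t], 1)
    beta += rng.normal(0.0, 0.5, size=(G, T))
    u = np.zeros((I, T))
    p = np.zeros((P, T))
    Sigma = np.tile(np.eye(T) * 0.5, (G, 1, 1)) * np.exp(rng.normal(0, 0.3, (G, 1, 1)))
    Sigma_pop = np.eye(T) * 0.25
    a_sig = np.ones((G, T))
    a_pop = np.ones(T)
    sig2_W = np.full((G, T), 0.5) * np.exp(rng.normal(0, 0.3, (G, T)))

    ind_lists = [np.flatnonzero(ind_group == g) for g in range(G)]
    # contiguous orderings for groupwise sums via add.reduceat
    ind_order = np.argsort(ind_group, kind="stable")
    m_ind = np.bincount(ind_group, minlength=G).astype(float)
    ind_starts = np.concatenate([[0], np.cumsum(m_ind.astype(int))[:-1]])
    pop_order = np.argsort(data["pop_group"], kind="stable")
    m_pop = np.bincount(data["pop_group"], minlength=G).astype(float)
    pop_starts = np.concatenate([[0], np.cumsum(m_pop.astype(int))[:-1]])
    kept = spec.mcmc.iterations - spec.mcmc.warmup
    out = {
        "beta": np.empty((kept, G, T)),
        "Sigma": np.empty((kept, G, T, T)),
        "sigma2_W": np.empty((kept, G, T)),
        "u": np.empty((kept, I, T)),
    }
    if include_pop:
        out["Sigma_Pop"] = np.empty((kept, T, T))
        out["p"] = np.empty((kept, P, T))

    eye = np.eye(T)
    for it in range(spec.mcmc.iterations):
        # --- group means, per trait (conjugate normal) ---
        for t in range(T):
            d = per[t]
            inv_w = 1.0 / sig2_W[d["g_obs"], t]
            r = d["y"] - u[d["i_obs"], t]
            if include_pop:
                r = r - p[d["k_obs"], t]
            prec = np.bincount(d["g_obs"], inv_w, minlength=G) + pr.beta_sd ** -2
            mean = np.bincount(d["g_obs"], r * inv_w, minlength=G) / prec
            beta[:, t] = mean + rng.standard_normal(G) / np.sqrt(prec)

        # --- individual effect vectors (batched 3x3 MVN) ---
        s_it = np.zeros((I, T))
        for t in range(T):
            d = per[t]
            r = d["y"] - beta[d["g_obs"], t]
            if include_pop:
                r = r - p[d["k_obs"], t]
            s_it[:, t] = np.bincount(d["i_obs"], r, minlength=I)
        inv_sig2w_ind = 1.0 / sig2_W[ind_group]  # (I, T)
        w = n_it * inv_sig2w_ind
        b = s_it * inv_sig2w_ind
        Lambda = np.linalg.inv(Sigma)  # (G, T, T)
        prec = Lambda[ind_group].copy()
        prec[:, np.arange(T), np.arange(T)] += w
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, b[:, :, None])[:, :, 0]
        z = rng.standard_normal((I, T, 1))
        noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), z)[:, :, 0]
        u = mean + noise

        # --- among-individual covariances (Huang-Wand inverse-Wishart) ---
        for g in range(G):
            ug = u[ind_lists[g]]
            scale = 2.0 * nu_c * np.diag(1.0 / a_sig[g]) + ug.T @ ug
            df = nu_c + T - 1 + len(ind_lists[g])
            Sigma[g] = invwishart.rvs(df=df, scale=scale, random_state=rng)
            lam_diag = np.diag(np.linalg.inv(Sigma[g]))
            a_sig[g] = _inv_gamma(
                rng, 0.5 * (nu_c + T), nu_c * lam_diag + A_c ** -2
            )

        if include_pop:
            # --- population effect vectors ---
            s_kt = np.zeros((P, T))
            for t in range(T):
                d = per[t]
                r = d["y"] - beta[d["g_obs"], t] - u[d["i_obs"], t]
                s_kt[:, t] = np.bincount(d["k_obs"], r, minlength=P)
            n_kt = np.zeros((P, T))
            for t in range(T):
                n_kt[:, t] = np.bincount(per[t]["k_obs"], minlength=P)
            inv_w_pop = 1.0 / sig2_W[data["pop_group"]]
            wp = n_kt * inv_w_pop
            bp = s_kt * inv_w_pop
            Lam_p = np.linalg.inv(Sigma_pop)
            prec = np.tile(Lam_p, (P, 1, 1))
            prec[:, np.arange(T), np.arange(T)] += wp
            Lp = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, bp[:, :, None])[:, :, 0]
            z = rng.standard_normal((P, T, 1))
            p = mean + np.linalg.solve(np.transpose(Lp, (0, 2, 1)), z)[:, :, 0]

            scale = 2.0 * nu_c * np.diag(1.0 / a_pop) + p.T @ p
            Sigma_pop = invwishart.rvs(df=nu_c + T - 1 + P, scale=scale, random_state=rng)
            lam_diag = np.diag(np.linalg.inv(Sigma_pop))
            a_pop = _inv_gamma(rng, 0.5 * (nu_c + T), nu_c * lam_diag + A_c ** -2)

        # --- location interweave for beta (centered random effects) ---
        c = beta[ind_group] + u
        Lambda = np.linalg.inv(Sigma)
        prec_b = m_ind[:, None, None] * Lambda + eye * pr.beta_sd ** -2
        rhs = np.einsum("gij,gj->gi", Lambda, np.add.reduceat(c[ind_order], ind_starts))
        Lb = np.linalg.cholesky(prec_b)
        mean_b = np.linalg.solve(prec_b, rhs[:, :, None])[:, :, 0]
        zb = rng.standard_normal((G, T, 1))
        beta = mean_b + np.linalg.solve(np.transpose(Lb, (0, 2, 1)), zb)[:, :, 0]
        u = c - beta[ind_group]
        if include_pop:
            c = beta[data["pop_group"]] + p
            Lam_p = np.linalg.inv(Sigma_pop)
            prec_b = m_pop[:, None, None] * Lam_p + eye * pr.beta_sd ** -2
            rhs = np.einsum(
                "ij,gj->gi", Lam_p, np.add.reduceat(c[pop_order], pop_starts)
            )
            Lb = np.linalg.cholesky(prec_b)
            mean_b = np.linalg.solve(prec_b, rhs[:, :, None])[:, :, 0]
            zb = rng.standard_normal((G, T, 1))
            beta = mean_b + np.linalg.solve(np.transpose(Lb, (0, 2, 1)), zb)[:, :, 0]
            p = c - beta[data["pop_group"]]

        # --- residual variances per group x trait ---
        ss = np.zeros((G, T))
        for t in range(T):
            d = per[t]
            r = d["y"] - beta[d["g_obs"], t] - u[d["i_obs"], t]
            if include_pop:
                r = r - p[d["k_obs"], t]
            ss[:, t] = np.bincount(d["g_obs"], r ** 2, minlength=G)
        sig2_W = _update_halft_variance(rng, ss, n_gt, sig2_W, nu_r, A_r)

        if it >= spec.mcmc.warmup:
            s = it - spec.mcmc.warmup
            out["beta"][s] = beta
            out["Sigma"][s] = Sigma
            out["sigma2_W"][s] = sig2_W
            out["u"][s] = u
            if include_pop:
                out["Sigma_Pop"][s] = Sigma_pop
                out["p"][s] = p
    return out


def fit_multivariate(table: ModelTable, spec: MultivariateSpec | None = None) -> MultivariateFit:
    """Fit the multi-response model by blocked Gibbs sampling.

    Traits may have per-response missingness (an individual can lack trials
    for some traits); individuals absent from every trait are simply not part
    of the table.
    """
    spec = spec or MultivariateSpec()
    spec.validate()
    data, obs_index = _prepare(table)
    t0 = time.perf_counter()
    seeds = np.random.SeedSequence(spec.mcmc.seed).spawn(spec.mcmc.chains)
    chains = [_run_mv_chain(data, spec, np.random.default_rng(s)) for s in seeds]
    draws = {name: np.stack([c[name] for c in chains]) for name in chains[0]}
    return MultivariateFit(
        draws=draws,
        coords={
            "groups": data["groups"],
            "individuals": data["individuals"],
            "populations": data["populations"],
        },
        spec=spec,
        traits=data["traits"],
        obs_index=obs_index,
        seed=spec.mcmc.seed,
        runtime_s=time.perf_counter() - t0,
        _data=data,
    )


@dataclass
class SyndromeReport:
    """Per-group among-individual correlation summaries; a pair is a
    "syndrome" in a group when its 95% CI excludes zero."""

    groups: list[str]
    traits: list[str]
    corr_draws: np.ndarray  # (S, G, T, T)
    frame: pd.DataFrame

    def correlation(self, group: str, trait_a: str, trait_b: str) -> pd.Series:
        sel = self.frame[
            (self.frame["group"] == group)
            & (self.frame["trait_a"] == trait_a)
            & (self.frame["trait_b"] == trait_b)
        ]
        if len(sel) != 1:
            raise KeyError(f"no correlation for ({trait_a}, {trait_b}) in {group}")
        return sel.iloc[0]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def among_individual_correlations(fit: MultivariateFit) -> SyndromeReport:
    """Convert each draw's per-group covariance into a correlation matrix and
    summarize every trait pair."""
    Sigma = fit.stacked("Sigma")  # (S, G, T, T)
    S, G, T, _ = Sigma.shape
    # PSD sanity on a thinned subset (draws come from an inverse-Wishart, so a
    # violation indicates a parameterization bug)
    check = Sigma[:: max(1, S // 64)]
    if np.linalg.eigvalsh(check).min() < -1e-8:
        raise ValueError("non-PSD covariance draw encountered")
    sd = np.sqrt(np.einsum("sgtt->sgt", Sigma))
    corr = Sigma / (sd[:, :, :, None] * sd[:, :, None, :])
    rows = []
    for g, glab in enumerate(fit.coords["groups"]):
        for a in range(T):
            for b in range(a + 1, T):
                vec = corr[:, g, a, b]
                med, lo, hi = summarize_draws(vec)
                rows.append(
                    {
                        "group": glab,
                        "trait_a": fit.traits[a],
                        "trait_b": fit.traits[b],
                        "median": med,
                        "mean": float(vec.mean()),
                        "lo": lo,
                        "hi": hi,
                        "syndrome": bool(lo > 0 or hi < 0),
                    }
                )
    return SyndromeReport(
        groups=list(fit.coords["groups"]),
        traits=list(fit.traits),
        corr_draws=corr,
        frame=pd.DataFrame(rows),
    )
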