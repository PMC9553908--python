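"""WAIC and PSIS-LOO model comparison from pointwise log-likelihood matrices.

Both criteria operate on a matrix ``loglik`` of shape (draws, observations)
whose entry (s, j) is the log-density of observation j under posterior draw s.

WAIC:  lpd_j = log mean_s exp(loglik[s, j]) (log-sum-exp, stable);
       p_waic_j = var_s loglik[s, j];  elpd_waic = sum_j (lpd_j - p_waic_j);
       WAIC = -2 elpd_waic.

PSIS-LOO: importance ratios 1/p(y_j | theta_s) are stabilized by fitting a
generalized Pareto distribution to the largest 20% of ratios (at most
3*sqrt(S) of them) and replacing the tail by its expected order statistics,
following the standard published PSIS recipe; the tail shape k is reported
per observation with the usual 0.5 / 0.7 reliability thresholds.

Lower WAIC / LOOIC (equivalently higher elpd) indicates better expected
predictive fit.  ``compare_models`` ranks candidate fits by elpd_loo (ties
broken by elpd_waic, then by fewer variance parameters).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .varmodel import PosteriorFit


@dataclass(frozen=True)
class WaicResult:
    elpd_waic: float
    p_waic: float
    waic: float
    se: float
    pointwise_elpd: np.ndarray

    def __iter__(self):
        return iter((self.elpd_waic, self.p_waic, self.waic, self.se))


@dataclass(frozen=True)
class LooResult:
    elpd_loo: float
    p_loo: float
    looic: float
    se: float
    pareto_k: np.ndarray
    pointwise_elpd: np.ndarray

    def __iter__(self):
        return iter((self.elpd_loo, self.p_loo, self.looic, self.se, self.pareto_k))

    def k_counts(self) -> dict[str, int]:
        """Pareto-k reliability counts with the 0.5 / 0.7 thresholds."""
        k = self.pareto_k
        return {
            "good": int(np.sum(k <= 0.5)),
            "ok": int(np.sum((k > 0.5) & (k <= 0.7))),
            "bad": int(np.sum(k > 0.7)),
        }


def _check_loglik(loglik: np.ndarray, min_draws: int = 2) -> np.ndarray:
    ll = np.asarray(loglik, float)
    if ll.ndim != 2:
        raise ValueError("loglik must be 2-D (draws x observations)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("loglik contains non-finite entries")
    if ll.shape[0] < min_draws:
        raise ValueError(f"need >= {min_draws} draws, got {ll.shape[0]}")
    return ll


def waic(loglik: np.ndarray) -> WaicResult:
    """Widely applicable information criterion from a (draws x obs) matrix."""
    ll = _check_loglik(loglik, min_draws=2)
    S, n = ll.shape
    lpd = logsumexp(ll, axis=0) - np.log(S)
    p_j = ll.var(axis=0, ddof=1)
    elpd_j = lpd - p_j
    elpd = float(elpd_j.sum())
    se = float(np.sqrt(n * elpd_j.var(ddof=1))) if n > 1 else 0.0
    if np.any(p_j > 0.4):
        warnings.warn(
            f"{int(np.sum(p_j > 0.4))} observation(s) with p_waic > 0.4; "
            "WAIC may be unreliable for them",
            stacklevel=2,
        )
    return WaicResult(elpd, float(p_j.sum()), -2.0 * elpd, se, elpd_j)


# ---------------------------------------------------------------------------
# Pareto-smoothed importance sampling
# ---------------------------------------------------------------------------

def _gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Fit a generalized Pareto to exceedances ``x`` (sorted ascending) by the
    empirical-Bayes profile-likelihood method of Zhang & Stephens (2009), with
    the weak shape prior used by the PSIS recipe.  Returns (k, sigma) in the
    xi-parameterization used by the quantile function below."""
    n = len(x)
    prior_bs, prior_k = 3.0, 10.0
    m = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m / (np.arange(1, m + 1, dtype=float) - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k = np.mean(np.log1p(-b[:, None] * x), axis=1)
    profile_ll = n * (np.log(-(b / k)) - k - 1.0)
    weights = np.exp(profile_ll - profile_ll.max())
    weights /= weights.sum()
    keep = weights >= 10 * np.finfo(float).eps
    b, weights = b[keep], weights[keep]
    b_post = float(np.sum(b * weights) / np.sum(weights))
    k_post = float(np.mean(np.log1p(-b_post * x)))
    sigma = -k_post / b_post
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return k_post, sigma


def _gpd_quantiles(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    """Inverse CDF of the generalized Pareto (location 0)."""
    if sigma <= 0:
        return np.full_like(p, np.nan)
    if np.abs(k) < np.finfo(float).eps:
        return -sigma * np.log1p(-p)
    return sigma * np.expm1(-k * np.log1p(-p)) / k


def smooth_log_weights(log_ratios: np.ndarray, reff: float = 1.0) -> tuple[np.ndarray, float]:
    """Pareto-smooth one vector of log importance ratios.

    Returns self-normalized log weights and the fitted tail shape k.  When the
    upper tail is too short (< 5 points) or has no spread — e.g. all ratios
    identical — smoothing is skipped, the exact normalized weights are
    returned, and k = -inf.
    """
    x = np.array(log_ratios, float)
    S = len(x)
    x -= x.max()
    k = -np.inf
    cutoff_ind = -int(np.ceil(min(0.2 * S, 3.0 * np.sqrt(S / reff)))) - 1
    if -cutoff_ind - 1 >= 5:
        srt = np.argsort(x)
        cutoff = max(x[srt[cutoff_ind]], np.log(np.finfo(float).tiny))
        (tail_ids,) = np.where(x > cutoff)
        if len(tail_ids) >= 5:
            order = np.argsort(x[tail_ids])
            tail = np.exp(x[tail_ids][order]) - np.exp(cutoff)
            if tail[-1] > 0:
                k, sigma = _gpd_fit(tail)
                if np.isfinite(k):
                    probs = (np.arange(0.5, len(tail_ids))) / len(tail_ids)
                    smoothed = np.log(_gpd_quantiles(probs, k, sigma) + np.exp(cutoff))
                    x[tail_ids[order]] = smoothed
                    np.minimum(x, 0.0, out=x)
    x -= logsumexp(x)
    return x, float(k)


def psis_loo(loglik: np.ndarray, reff: float = 1.0) -> LooResult:
    """PSIS leave-one-out expected log predictive density.

    elpd_loo_j = log sum_s w_sj exp(loglik[s, j]) with self-normalized
    Pareto-smoothed weights w_sj derived from the ratios exp(-loglik[s, j]).
    """
    ll = _check_loglik(loglik, min_draws=2)
    S, n = ll.shape
    if S < 100:
        warnings.warn(f"PSIS-LOO with only {S} draws; >= 100 recommended", stacklevel=2)
    elpd_j = np.empty(n)
    ks = np.empty(n)
    for j in range(n):
        lw, k = smooth_log_weights(-ll[:, j], reff=reff)
        elpd_j[j] = logsumexp(lw + ll[:, j])
        ks[j] = k
    lpd = logsumexp(ll, axis=0) - np.log(S)
    elpd = float(elpd_j.sum())
    p_loo = float((lpd - elpd_j).sum())
    se = float(np.sqrt(n * elpd_j.var(ddof=1))) if n > 1 else 0.0
    if np.any(ks > 0.7):
        warnings.warn(
            f"{int(np.sum(ks > 0.7))} observation(s) with Pareto k > 0.7; "
            "their LOO contributions are unreliable",
            stacklevel=2,
        )
    return LooResult(elpd, p_loo, -2.0 * elpd, se, ks, elpd_j)


# ---------------------------------------------------------------------------
# model ranking
# ---------------------------------------------------------------------------

@dataclass
class ComparisonTable:
    """Per-model criteria, ranking, pairwise elpd differences, and the
    selected model."""

    frame: pd.DataFrame
    pairwise: pd.DataFrame
    selected: str
    criterion: str

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "criterion": self.criterion,
            "selected": self.selected,
            "models": self.frame.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def compare_models(
    fits: list[PosteriorFit],
    criterion: str = "loo",
    reff: float = 1.0,
) -> ComparisonTable:
    """Rank candidate fits of the same data by elpd.

    Primary criterion is elpd_loo (``criterion="waic"`` switches); exact ties
    are broken by the other criterion, then by fewer variance parameters.
    All fits must be trained on the identical observation set.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to compare")
    if criterion not in ("loo", "waic"):
        raise ValueError("criterion must be 'loo' or 'waic'")
    ref = fits[0].obs_index
    for fit in fits[1:]:
        if len(fit.obs_index) != len(ref) or not fit.obs_index.reset_index(drop=True).equals(
            ref.reset_index(drop=True)
        ):
            raise ValueError("fits were trained on different observation sets")

    rows = []
    loo_results, waic_results = [], []
    for fit in fits:
        w = waic(fit.loglik)
        l = psis_loo(fit.loglik, reff=reff)
        loo_results.append(l)
        waic_results.append(w)
        n_groups = len(fit.coords["groups"])
        rows.append(
            {
                "model": fit.spec.label,
                "structure": fit.spec.variance_structure,
                "n_variance_params": fit.spec.n_variance_params(n_groups),
                "elpd_loo": l.elpd_loo,
                "se_elpd_loo": l.se,
                "p_loo": l.p_loo,
                "looic": l.looic,
                "elpd_waic": w.elpd_waic,
                "se_elpd_waic": w.se,
                "p_waic": w.p_waic,
                "waic": w.waic,
                **{f"pareto_k_{kk}": v for kk, v in l.k_counts().items()},
            }
        )
    frame = pd.DataFrame(rows)

    primary = "elpd_loo" if criterion == "loo" else "elpd_waic"
    secondary = "elpd_waic" if criterion == "loo" else "elpd_loo"
    order = sorted(
        range(len(fits)),
        key=lambda i: (
            -round(frame[primary][i], 9),
            -round(frame[secondary][i], 9),
            frame["n_variance_params"][i],
        ),
    )
    frame = frame.iloc[order].reset_index(drop=True)
    frame.insert(1, "rank", np.arange(len(fits)))

    pointwise = [
        (loo_results if criterion == "loo" else waic_results)[i].pointwise_elpd for i in order
    ]
    labels = list(frame["model"])
    n = len(ref)
    pair_rows = []
    for a in range(len(fits)):
        for b in range(a + 1, len(fits)):
            d = pointwise[a] - pointwise[b]
            pair_rows.append(
                {
                    "model_a": labels[a],
                    "model_b": labels[b],
                    "elpd_diff": float(d.sum()),
                    "se_diff": float(np.sqrt(n * d.var(ddof=1))) if n > 1 else 0.0,
                }
            )
    pairwise = pd.DataFrame(pair_rows)
    return ComparisonTable(
        frame=frame, pairwise=pairwise, selected=labels[0], criterion=criterion
    )
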