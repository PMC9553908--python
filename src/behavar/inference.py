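"""Headline quantities from accepted fits: per-group variance components,
adjusted repeatability, pairwise variance/repeatability contrasts, and group
mean contrasts.

Adjusted short-term repeatability of a group, per posterior draw:

    R = V_A / (V_A + V_W + V_Pop)

with V_A the among-individual variance, V_W the within-individual (residual)
variance and V_Pop the among-population variance within the group (zero when
the model has no population term, as in the within-region analysis).  R > 0.5
means the majority of phenotypic variance is among individuals.

Delta contrasts between two groups a and b are plain draw-wise posterior
differences on the standardized-response scale (DV_A = V_A,a - V_A,b, and the
same for V_W and R); a contrast is flagged when its central 95% credible
interval excludes zero.  Point summaries are posterior medians (posterior
means are emitted alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .varmodel import ModelSpec, PosteriorFit


def summarize_draws(draws) -> tuple[float, float, float]:
    """(median, 2.5% quantile, 97.5% quantile) with type-7 linear
    interpolation (numpy's default)."""
    x = np.asarray(draws, float)
    if x.size < 2:
        raise ValueError("need >= 2 draws to summarize")
    med, lo, hi = np.quantile(x, [0.5, 0.025, 0.975], method="linear")
    return float(med), float(lo), float(hi)


def repeatability_draws(v_a, v_w, v_pop=None) -> np.ndarray:
    """Draw-wise adjusted repeatability V_A / (V_A + V_W + V_Pop)."""
    v_a = np.asarray(v_a, float)
    v_w = np.asarray(v_w, float)
    v_pop = np.zeros_like(v_a) if v_pop is None else np.asarray(v_pop, float)
    if not (v_a.shape == v_w.shape == v_pop.shape):
        raise ValueError("draw vectors must be aligned")
    if np.any(v_a < 0) or np.any(v_w < 0) or np.any(v_pop < 0):
        raise ValueError("variance draws must be nonnegative")
    denom = v_a + v_w + v_pop
    if np.any(denom <= 0):
        raise ValueError("zero total variance in at least one draw")
    return v_a / denom


def delta_contrasts(
    draws_a: np.ndarray,
    draws_b: np.ndarray,
) -> tuple[np.ndarray, dict[str, float]]:
    """Draw-wise difference a - b with its median / 95% CI summary.

    Caller is responsible for taking both draw vectors from the same fit (the
    higher-level report builders enforce this); the ordering convention for
    the regional analysis is native minus invasive.
    """
    a = np.asarray(draws_a, float)
    b = np.asarray(draws_b, float)
    if a.shape != b.shape:
        raise ValueError("contrast draw vectors must be aligned (same fit, same length)")
    d = a - b
    med, lo, hi = summarize_draws(d)
    return d, {
        "median": med,
        "mean": float(d.mean()),
        "lo": lo,
        "hi": hi,
        "ci_excludes_zero": bool(lo > 0 or hi < 0),
    }


@dataclass
class VarianceReport:
    """Per-group variance/repeatability summaries and pairwise contrasts for
    one trait."""

    trait: str
    groups: list[str]
    draws: dict[str, np.ndarray]  # "V_A[g]", "V_W[g]", "V_Pop", "R[g]" -> (S,)
    per_group: pd.DataFrame
    contrasts: pd.DataFrame

    def contrast_row(self, a: str, b: str, quantity: str) -> pd.Series:
        sel = self.contrasts[
            (self.contrasts["group_a"] == a)
            & (self.contrasts["group_b"] == b)
            & (self.contrasts["quantity"] == quantity)
        ]
        if len(sel) != 1:
            raise KeyError(f"no contrast {quantity}({a} - {b})")
        return sel.iloc[0]

    def to_contrast_csv(self, path) -> None:
        """Serialize contrasts in a wide layout: one row per group pair,
        columns DV_A / DV_W / DR with "(lo, hi)" interval strings and a bold
        flag marking CIs that exclude zero."""
        rows = {}
        for _, row in self.contrasts.iterrows():
            key = f"{row['group_a']} - {row['group_b']}"
            entry = rows.setdefault(key, {"contrast": key})
            q = row["quantity"]
            entry[q] = round(row["median"], 3)
            entry[f"{q}_CI"] = f"({row['lo']:.3f}, {row['hi']:.3f})"
            entry[f"{q}_excludes_zero"] = bool(row["ci_excludes_zero"])
        pd.DataFrame(list(rows.values())).to_csv(path, index=False)


def variance_summary(fit: PosteriorFit, spec: ModelSpec | None = None) -> VarianceReport:
    """Assemble variance components, repeatability, and all pairwise ordered
    contrasts from a fitted univariate model."""
    spec = spec or fit.spec
    if spec.trait != fit.spec.trait or spec.variance_structure != fit.spec.variance_structure:
        raise ValueError("spec does not match the fitted model")
    groups = fit.coords["groups"]
    v_a = fit.sigma2("A")  # (S, G), already variance scale
    v_w = fit.sigma2("W")
    v_pop = fit.sigma2("Pop")  # (S,)

    draws: dict[str, np.ndarray] = {"V_Pop": v_pop}
    per_rows = []
    for g, lab in enumerate(groups):
        r = repeatability_draws(v_a[:, g], v_w[:, g], v_pop)
        draws[f"V_A[{lab}]"] = v_a[:, g]
        draws[f"V_W[{lab}]"] = v_w[:, g]
        draws[f"R[{lab}]"] = r
        for qty, vec in (("V_A", v_a[:, g]), ("V_W", v_w[:, g]), ("R", r)):
            med, lo, hi = summarize_draws(vec)
            per_rows.append(
                {
                    "group": lab,
                    "quantity": qty,
                    "median": med,
                    "mean": float(vec.mean()),
                    "lo": lo,
                    "hi": hi,
                    **({"majority_among": med > 0.5} if qty == "R" else {}),
                }
            )
    med, lo, hi = summarize_draws(v_pop) if v_pop.any() else (0.0, 0.0, 0.0)
    per_rows.append(
        {"group": "(all)", "quantity": "V_Pop", "median": med,
         "mean": float(v_pop.mean()), "lo": lo, "hi": hi}
    )
    per_group = pd.DataFrame(per_rows)

    contrast_rows = []
    for a in groups:
        for b in groups:
            if a == b:
                continue
            for qty in ("V_A", "V_W", "R"):
                _, summ = delta_contrasts(draws[f"{qty}[{a}]"], draws[f"{qty}[{b}]"])
                contrast_rows.append(
                    {"group_a": a, "group_b": b, "quantity": f"D{qty}", **summ}
                )
    contrasts = pd.DataFrame(contrast_rows)
    return VarianceReport(
        trait=fit.spec.trait,
        groups=list(groups),
        draws=draws,
        per_group=per_group,
        contrasts=contrasts,
    )


@dataclass
class MeanContrastReport:
    """Posterior group-mean differences on the standardized scale for one
    trait.  For boldness the stored draws are latency-scale; rendering code
    should flip the sign when ``invert_display`` is set so that higher =
    bolder."""

    trait: str
    groups: list[str]
    invert_display: bool
    contrasts: pd.DataFrame

    def display_frame(self) -> pd.DataFrame:
        """Contrast table on the display scale (boldness sign-flipped)."""
        df = self.contrasts.copy()
        if self.invert_display:
            med = -df["median"]
            mean = -df["mean"]
            lo, hi = -df["hi"], -df["lo"]
            df["median"], df["mean"], df["lo"], df["hi"] = med, mean, lo, hi
        return df

    def to_csv(self, path) -> None:
        self.display_frame().to_csv(path, index=False)


def mean_contrasts(fit: PosteriorFit) -> MeanContrastReport:
    """Pairwise posterior differences of group means beta_a - beta_b."""
    groups = fit.coords["groups"]
    beta = fit.stacked("beta")
    rows = []
    for ai, a in enumerate(groups):
        for bi, b in enumerate(groups):
            if a == b:
                continue
            _, summ = delta_contrasts(beta[:, ai], beta[:, bi])
            rows.append({"group_a": a, "group_b": b, **summ})
    return MeanContrastReport(
        trait=fit.spec.trait,
        groups=list(groups),
        invert_display=fit.spec.trait == "boldness",
        contrasts=pd.DataFrame(rows),
    )
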