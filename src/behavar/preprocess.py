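"""Filtering, transformation and standardization of raw trial data.

Rules applied, in order, per trait:

1. drop trials where the animal never moved (activity and exploration assays
   only — a no-movement boldness trial is still a valid latency) and trials
   whose recording failed (all traits);
2. variance-stabilizing transform: square root for activity and exploration,
   log10 for boldness latency;
3. z-standardization (mean 0, SD 1, sample SD with n-1 denominator) computed
   per trait over the full retained dataset with all groups pooled.
   Standardizing within groups would erase exactly the group mean differences
   the models estimate, so pooled constants are the only defensible choice.

The boldness display inversion (higher = bolder) is a reporting-time sign
flip; models are always fitted on (transformed) latency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Dataset

TABLE_COLUMNS = ["group", "population", "individual", "trait", "trial", "y"]

_TRANSFORM_NAMES = {"activity": "sqrt", "exploration": "sqrt", "boldness": "log10"}


class PreprocessError(ValueError):
    pass


def filter_trials(dataset: Dataset) -> tuple[Dataset, pd.DataFrame]:
    """Drop invalid trials; return the retained dataset and a per-trait summary.

    Removes activity/exploration rows with ``moved = False`` and rows of any
    trait with ``recorded = False``.  Raises if any trait present in the input
    would be left with no rows.
    """
    df = dataset.frame
    unmoved = (~df["moved"]) & df["trait"].isin(["activity", "exploration"])
    unrecorded = ~df["recorded"]
    keep = ~(unmoved | unrecorded)

    rows = []
    for trait, sub in df.groupby("trait", sort=True):
        retained = int(keep[sub.index].sum())
        if retained == 0:
            raise PreprocessError(f"no valid trials left for trait {trait!r} after filtering")
        rows.append(
            {
                "trait": trait,
                "n_input": len(sub),
                "n_removed_not_moved": int((unmoved[sub.index]).sum()),
                "n_removed_not_recorded": int((unrecorded & ~unmoved)[sub.index].sum()),
                "n_retained": retained,
            }
        )
    summary = pd.DataFrame(rows)
    return Dataset(df[keep].reset_index(drop=True)), summary


def transform_trait(values, trait: str) -> np.ndarray:
    """Variance-stabilizing transform: sqrt (activity, exploration) or log10
    (boldness)."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise PreprocessError(f"{trait}: raw values must be nonnegative")
    if trait in ("activity", "exploration"):
        return np.sqrt(x)
    if trait == "boldness":
        if np.any(x == 0):
            raise PreprocessError(
                "boldness: latency of 0 s is invalid (emergence cannot precede release)"
            )
        return np.log10(x)
    raise PreprocessError(f"unknown trait {trait!r}")


def standardize_trait(values) -> tuple[np.ndarray, float, float]:
    """Z-score with the sample SD (ddof=1); returns (z, mean, sd)."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise PreprocessError("standardization requires >= 2 distinct values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise PreprocessError("standardization requires nonzero SD")
    return (x - mean) / sd, mean, sd


@dataclass(frozen=True)
class TraitTransform:
    """Record of the transform and standardization constants used for a trait,
    sufficient to reapply or invert the y-scale mapping."""

    trait: str
    transform: str
    mean: float
    sd: float

    def apply(self, raw_values) -> np.ndarray:
        return (transform_trait(raw_values, self.trait) - self.mean) / self.sd


@dataclass
class ModelTable:
    """Model-ready long table: one row per retained trial, response ``y`` on
    the standardized transformed scale."""

    frame: pd.DataFrame
    transforms: dict[str, TraitTransform]
    grouping: str
    filter_summary: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"ModelTable frame missing columns: {missing}")
        self.frame = self.frame[TABLE_COLUMNS].reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return sorted(self.frame["trait"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.frame[self.frame["trait"] == trait]
        if len(sub) == 0:
            raise KeyError(f"trait {trait!r} not present in table")
        return sub.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
        meta = {
            "grouping": self.grouping,
            "transforms": {
                t: {"transform": tr.transform, "mean": tr.mean, "sd": tr.sd}
                for t, tr in self.transforms.items()
            },
        }
        with open(str(path) + ".meta.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def from_csv(cls, path) -> "ModelTable":
        frame = pd.read_csv(path)
        with open(str(path) + ".meta.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        transforms = {
            t: TraitTransform(trait=t, transform=d["transform"], mean=d["mean"], sd=d["sd"])
            for t, d in meta["transforms"].items()
        }
        return cls(frame=frame, transforms=transforms, grouping=meta["grouping"])


def prepare_model_table(dataset: Dataset, grouping: str = "region") -> ModelTable:
    """Filter -> transform -> standardize, per trait.

    ``grouping`` selects the fixed-effect group label column: ``"region"`` for
    the regional analysis, ``"population"`` for the within-region analysis.
    """
    if grouping not in ("region", "population"):
        raise PreprocessError(f"grouping must be 'region' or 'population', got {grouping!r}")
    dataset.validate()
    filtered, summary = filter_trials(dataset)
    df = filtered.frame

    pieces = []
    transforms: dict[str, TraitTransform] = {}
    for trait, sub in df.groupby("trait", sort=True):
        z, mean, sd = standardize_trait(transform_trait(sub["value"].to_numpy(), trait))
        transforms[trait] = TraitTransform(
            trait=trait, transform=_TRANSFORM_NAMES[trait], mean=mean, sd=sd
        )
        piece = pd.DataFrame(
            {
                "group": sub["region" if grouping == "region" else "population"].to_numpy(),
                "population": sub["population"].to_numpy(),
                "individual": sub["individual"].to_numpy(),
                "trait": trait,
                "trial": sub["trial"].to_numpy(),
                "y": z,
            }
        )
        pieces.append(piece)
    frame = pd.concat(pieces, ignore_index=True)
    return ModelTable(frame=frame, transforms=transforms, grouping=grouping, filter_summary=summary)
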