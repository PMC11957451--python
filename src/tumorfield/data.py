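"""In-memory containers for the cohort data streams.

The cross-sectional survey is held as two aligned DataFrames: one row per
necropsied mouse (``mouse_id``, ``age_weeks``) and one row per observed
tumor (``mouse_id``, ``genotype``, ``area_mm2``).  Keeping mice separate
from tumors preserves tumor-free mice, which carry real information
(observed zero counts) for the transition-rate fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SurveyCohort", "classify_tumor", "state_counts"]

DEFAULT_CUTOFF_MM2 = 9.0
ALTERNATIVE_CUTOFF_MM2 = 1.5


def classify_tumor(area, cutoff: float = DEFAULT_CUTOFF_MM2):
    """Classify tumor area (mm^2) as screen-detectable "S" or palpable "L".

    The boundary is inclusive on the palpable side: ``area >= cutoff -> "L"``.
    Vectorized over ``area``.
    """
    if not cutoff > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("tumor areas must be positive")
    out = np.where(area >= cutoff, "L", "S")
    return out if out.ndim else str(out)


@dataclass(frozen=True)
class SurveyCohort:
    """A cross-sectional necropsy survey: mice and their tumors."""

    mice: pd.DataFrame  # columns: mouse_id, age_weeks
    tumors: pd.DataFrame  # columns: mouse_id, genotype, area_mm2

    def __post_init__(self) -> None:
        for col in ("mouse_id", "age_weeks"):
            if col not in self.mice.columns:
                raise ValueError(f"mice table missing column {col!r}")
        for col in ("mouse_id", "genotype", "area_mm2"):
            if col not in self.tumors.columns:
                raise ValueError(f"tumors table missing column {col!r}")
        if self.mice["mouse_id"].duplicated().any():
            raise ValueError("mice table has duplicated mouse_id")
        orphans = set(self.tumors["mouse_id"]) - set(self.mice["mouse_id"])
        if orphans:
            raise ValueError(f"tumors reference unknown mice: {sorted(orphans)[:5]}")

    @property
    def n_mice(self) -> int:
        return len(self.mice)

    def genotypes(self) -> list[str]:
        return sorted(self.tumors["genotype"].unique())

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the survey.csv schema (one row per tumor).

        Tumor-free mice appear as a single row with empty genotype and
        missing area so that no observed zero count is lost on round-trip.
        """
        merged = self.tumors.merge(self.mice, on="mouse_id", how="left")
        merged = merged[["mouse_id", "age_weeks", "genotype", "area_mm2"]]
        tumor_free = self.mice[~self.mice["mouse_id"].isin(self.tumors["mouse_id"])]
        if len(tumor_free):
            blanks = tumor_free.assign(genotype="", area_mm2=np.nan)
            merged = pd.concat(
                [merged, blanks[["mouse_id", "age_weeks", "genotype", "area_mm2"]]],
                ignore_index=True,
            )
        return merged.sort_values(["mouse_id"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurveyCohort":
        """Rebuild from the flat survey.csv schema."""
        mice = (
            df[["mouse_id", "age_weeks"]]
            .drop_duplicates("mouse_id")
            .reset_index(drop=True)
        )
        has_tumor = df["area_mm2"].notna() & (df["genotype"].fillna("") != "")
        tumors = df.loc[has_tumor, ["mouse_id", "genotype", "area_mm2"]].reset_index(
            drop=True
        )
        return cls(mice=mice, tumors=tumors)


def state_counts(
    cohort: SurveyCohort, genotype: str, cutoff: float = DEFAULT_CUTOFF_MM2
) -> pd.DataFrame:
    """Per-mouse S and L tumor counts for one genotype.

    Returns a DataFrame with one row per mouse in the cohort (including
    tumor-free mice) and columns ``mouse_id, age_weeks, S, L``.
    """
    sel = cohort.tumors[cohort.tumors["genotype"] == genotype]
    if len(sel):
        states = classify_tumor(sel["area_mm2"].to_numpy(), cutoff)
        counts = (
            pd.DataFrame({"mouse_id": sel["mouse_id"].to_numpy(), "state": states})
            .pivot_table(index="mouse_id", columns="state", aggfunc="size", fill_value=0)
            .reset_index()
        )
    else:
        counts = pd.DataFrame({"mouse_id": []})
    out = cohort.mice.merge(counts, on="mouse_id", how="left")
    for col in ("S", "L"):
        if col not in out.columns:
            out[col] = 0
    out[["S", "L"]] = out[["S", "L"]].fillna(0).astype(int)
    return out[["mouse_id", "age_weeks", "S", "L"]]
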