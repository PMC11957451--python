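"""CSV/JSON readers and writers with schema validation.

All tabular artifacts are UTF-8 comma-separated files with a header row.
Ages are in weeks for the digestion and survey schemas and in days for
palpation, mirroring how the source data streams are recorded; the
conversion lives here and nowhere else.  Validation errors name the
offending row (0-based data row, excluding the header).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SurveyCohort
from .metrics import PalpationSeries
from .presets import MUTATION_TYPE_COLUMNS

__all__ = [
    "SchemaError",
    "read_digestion",
    "write_digestion",
    "read_survey",
    "write_survey",
    "read_palpation",
    "write_palpation",
    "read_mutations",
    "write_mutations",
    "write_json",
]

WEEKS_PER_DAY = 1.0 / 7.0


class SchemaError(ValueError):
    """A table violates its schema; the message names the row."""


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns {missing}")


def _first_bad_row(mask: pd.Series) -> int:
    return int(np.nonzero(mask.to_numpy())[0][0])


def read_digestion(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["mouse_id", "age_weeks", "genotype", "cell_count", "total_fluorescent"],
        "digestion table",
    )
    bad = (df["cell_count"] < 0) | (df["cell_count"] > df["total_fluorescent"])
    if bad.any():
        raise SchemaError(
            f"digestion row {_first_bad_row(bad)}: cell_count must satisfy "
            "0 <= cell_count <= total_fluorescent"
        )
    if (df["age_weeks"] <= 0).any():
        raise SchemaError(
            f"digestion row {_first_bad_row(df['age_weeks'] <= 0)}: "
            "age_weeks must be positive"
        )
    return df


def write_digestion(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_survey(path) -> SurveyCohort:
    df = pd.read_csv(path)
    _require_columns(
        df, ["mouse_id", "age_weeks", "genotype", "area_mm2"], "survey table"
    )
    has_tumor = df["area_mm2"].notna()
    bad = has_tumor & (df["area_mm2"] <= 0)
    if bad.any():
        raise SchemaError(
            f"survey row {_first_bad_row(bad)}: area_mm2 must be positive"
        )
    if (df["age_weeks"] <= 0).any():
        raise SchemaError(
            f"survey row {_first_bad_row(df['age_weeks'] <= 0)}: "
            "age_weeks must be positive"
        )
    df = df.copy()
    df["genotype"] = df["genotype"].fillna("")
    return SurveyCohort.from_frame(df)


def write_survey(cohort: SurveyCohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def read_palpation(path) -> list[PalpationSeries]:
    df = pd.read_csv(path)
    _require_columns(
        df, ["tumor_id", "genotype", "age_days", "volume_mm3"], "palpation table"
    )
    bad = df["volume_mm3"] <= 0
    if bad.any():
        raise SchemaError(
            f"palpation row {_first_bad_row(bad)}: volume_mm3 must be positive"
        )
    out = []
    for tid, grp in df.groupby("tumor_id", sort=False):
        grp = grp.sort_values("age_days")
        out.append(
            PalpationSeries(
                tumor_id=str(tid),
                genotype=str(grp["genotype"].iloc[0]),
                age_days=grp["age_days"].to_numpy(dtype=float),
                volume_mm3=grp["volume_mm3"].to_numpy(dtype=float),
            )
        )
    return out


def write_palpation(series: list[PalpationSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "tumor_id": s.tumor_id,
                "genotype": s.genotype,
                "age_days": s.age_days,
                "volume_mm3": s.volume_mm3,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_mutations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, ["genotype", "size_class"] + MUTATION_TYPE_COLUMNS + ["total"],
        "mutation table",
    )
    bad = df[MUTATION_TYPE_COLUMNS].sum(axis=1) != df["total"]
    if bad.any():
        raise SchemaError(
            f"mutation row {_first_bad_row(bad)}: total != sum of type counts"
        )
    return df


def write_mutations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
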