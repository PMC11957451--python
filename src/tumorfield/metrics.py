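"""Descriptive analytics of the observable phase of tumorigenesis.

Covers tumor volume doubling time (TVDT) from longitudinal caliper
palpation, back-extrapolated initiation age, the palpable-size cutoff
derived from the lower percentile of palpable tumor areas, the
palpable/unpalpable classification report, product-limit (Kaplan–Meier)
tumor-free survival, and mutation-burden summaries of whole-exome counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PalpationSeries",
    "SurvivalCurve",
    "tvdt",
    "initiation_age",
    "derive_cutoff",
    "classification_report",
    "tumor_free_survival",
    "mutation_summary",
    "caliper_volume",
    "projected_area",
]

#: Back-extrapolation target volume: roughly one cell, in mm^3.  The
#: choice is consequential (it sets how many doublings are rewound), so
#: callers should log the value they use.
DEFAULT_REFERENCE_VOLUME_MM3 = 1e-6


@dataclass(frozen=True)
class PalpationSeries:
    """Longitudinal caliper volumes for one tumor."""

    tumor_id: str
    genotype: str
    age_days: np.ndarray
    volume_mm3: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.age_days, dtype=float)
        vols = np.asarray(self.volume_mm3, dtype=float)
        if ages.shape != vols.shape or ages.ndim != 1:
            raise ValueError("age_days and volume_mm3 must be 1-D and aligned")
        if ages.size and not np.all(np.diff(ages) > 0):
            raise ValueError("measurement ages must be strictly increasing")
        if np.any(vols <= 0):
            raise ValueError("volumes must be positive")
        object.__setattr__(self, "age_days", ages)
        object.__setattr__(self, "volume_mm3", vols)

    @property
    def n_measurements(self) -> int:
        return self.age_days.size


def caliper_volume(length_mm, width_mm):
    """Standard caliper volume V = L * W^2 / 2 (mm^3)."""
    return np.asarray(length_mm, float) * np.asarray(width_mm, float) ** 2 / 2.0


def projected_area(length_mm, width_mm):
    """Projected elliptical area A = pi * L * W / 4 (mm^2).

    This is the conversion behind relating caliper measurements to
    imaging areas; both conventions live here so the size-cutoff pipeline
    can be re-based on either.
    """
    return np.pi * np.asarray(length_mm, float) * np.asarray(width_mm, float) / 4.0


def tvdt(series: PalpationSeries, min_measurements: int = 3) -> float | None:
    """Tumor volume doubling time in days, or None when excluded.

    Least-squares slope ``b`` of ln(volume) on age gives TVDT = ln2 / b.
    Series with fewer than ``min_measurements`` points are excluded
    (None), as are series with non-positive growth slope, for which a
    doubling time is undefined.
    """
    if series.n_measurements < min_measurements:
        return None
    b = np.polyfit(series.age_days, np.log(series.volume_mm3), 1)[0]
    # slopes at rounding-noise level (flat series) are as undefined as
    # negative ones
    if b <= 1e-12:
        return None
    return float(np.log(2.0) / b)


def initiation_age(
    series: PalpationSeries,
    tvdt_days: float,
    reference_volume: float = DEFAULT_REFERENCE_VOLUME_MM3,
) -> float:
    """Back-extrapolated initiation age (days) at the reference volume.

    Assumes a constant doubling time:
    ``t_init = t_first - TVDT * log2(V_first / V_ref)``.
    """
    if reference_volume <= 0:
        raise ValueError("reference_volume must be positive")
    if not tvdt_days > 0:
        raise ValueError("tvdt_days must be positive")
    v_first = float(series.volume_mm3[0])
    t_first = float(series.age_days[0])
    if v_first < reference_volume:
        raise ValueError(
            "first measured volume is below the reference volume; "
            "back-extrapolation is meaningless"
        )
    return t_first - tvdt_days * np.log2(v_first / reference_volume)


def derive_cutoff(palpable_areas, percentile: float = 15.0) -> float:
    """Size cutoff (mm^2) = the given percentile of palpable tumor areas.

    Uses the linear-interpolation percentile definition.
    """
    areas = np.asarray(palpable_areas, dtype=float)
    if areas.size == 0:
        raise ValueError("palpable_areas must be non-empty")
    return float(np.percentile(areas, percentile, method="linear"))


def classification_report(
    areas, palpated: np.ndarray, cutoff: float
) -> dict[str, float | None]:
    """Per-class accuracy of the ``area >= cutoff`` palpability rule.

    ``palpated`` is the true label (True = palpable).  Returns accuracies
    for both classes; a class with no members is reported as None rather
    than 0.
    """
    areas = np.asarray(areas, dtype=float)
    palpated = np.asarray(palpated, dtype=bool)
    predicted_palpable = areas >= cutoff
    out: dict[str, float | None] = {}
    for label, mask, pred in (
        ("palpable", palpated, predicted_palpable),
        ("unpalpable", ~palpated, ~predicted_palpable),
    ):
        out[label] = float(np.mean(pred[mask])) if mask.any() else None
    return out


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival curve with its median event time."""

    times: np.ndarray  # days
    survival: np.ndarray
    n_at_risk: np.ndarray
    median_time: float | None

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def tumor_free_survival(event_ages, censor_ages=()) -> SurvivalCurve:
    """Kaplan–Meier tumor-free survival from first-palpation ages (days).

    ``event_ages`` are ages at the first palpable tumor; ``censor_ages``
    are ages at censoring for tumor-free mice.  The median is the first
    observed time at which survival drops to 0.5 or below (None when the
    curve never reaches 0.5).
    """
    from lifelines import KaplanMeierFitter

    event_ages = np.asarray(event_ages, dtype=float)
    censor_ages = np.asarray(censor_ages, dtype=float)
    if np.any(event_ages < 0) or np.any(censor_ages < 0):
        raise ValueError("ages must be non-negative")
    durations = np.concatenate([event_ages, censor_ages])
    observed = np.concatenate(
        [np.ones_like(event_ages), np.zeros_like(censor_ages)]
    )
    if durations.size == 0:
        raise ValueError("no mice supplied")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(times[below[0]]) if below.size else None
    return SurvivalCurve(
        times=times, survival=surv, n_at_risk=at_risk, median_time=median
    )


_TYPE_COLUMNS = [
    "missense",
    "nonsense",
    "start_codon",
    "start_loss",
    "stop_loss",
    "frameshift",
    "in_frame",
]


def mutation_summary(rows: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Mean total mutation burden by genotype, size class, and both.

    ``rows`` must carry per-tumor type counts and a ``total`` column that
    equals their sum (validated row by row).  Means are truncated to
    integer for comparison with reported values.
    """
    bad = rows.index[rows[_TYPE_COLUMNS].sum(axis=1) != rows["total"]]
    if len(bad):
        raise ValueError(
            f"mutation rows {list(bad)} have total != sum of type counts"
        )

    def trunc_means(grouped) -> dict[str, int]:
        return {str(k): int(v) for k, v in grouped["total"].mean().items()}

    return {
        "by_genotype": trunc_means(rows.groupby("genotype")),
        "by_size_class": trunc_means(rows.groupby("size_class")),
        "by_genotype_and_size": {
            f"{g}_{s}": int(v)
            for (g, s), v in rows.groupby(["genotype", "size_class"])["total"]
            .mean()
            .items()
        },
        "grand_mean": int(rows["total"].mean()),
    }
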