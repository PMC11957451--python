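"""Synthetic cohort generation with the statistical structure the
analysis assumes.

Emulates the four experimental data streams feeding the pipeline:

* gland-digestion cell counts at weeks 3/4/6/10 of age — logistic field
  growth with multiplicative (mean-one log-normal) noise;
* a cross-sectional necropsy survey every 3.5 days from 10 to 20 weeks
  (120 mice by default) — per-mouse S and L tumor counts Poisson around
  the compartment-model expectations, with class-conditional areas;
* longitudinal caliper palpation — exponential tumor growth with a
  ~12-day doubling time measured twice weekly to a 2000 mm^3 endpoint;
* a whole-exome mutation-count table — negative-binomial totals by
  genotype and size class, multinomial across mutation types.

Every stream is deterministic given the config seed; the generators are
the test bed for the estimation machinery, not a model of real-data
artefacts (no measurement dropout, no between-mouse rate heterogeneity).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import presets
from .data import DEFAULT_CUTOFF_MM2, SurveyCohort
from .metrics import PalpationSeries
from .models import ModelSpec, expected_counts

__all__ = [
    "CohortConfig",
    "gen_digestion",
    "gen_survey",
    "gen_palpation",
    "gen_mutation_table",
]

# fixed per-stream identifiers so streams stay independent under one seed
_STREAM_DIGESTION, _STREAM_SURVEY, _STREAM_PALPATION, _STREAM_MUTATION = range(4)


def _default_specs() -> dict[str, ModelSpec]:
    return {g: presets.fsl_spec(g) for g in ("d16", "p95")}


def _default_mutation_means() -> dict[tuple[str, str], float]:
    # group means of the published exome table
    df = presets.mutation_table()
    return {
        (g, s): float(v)
        for (g, s), v in df.groupby(["genotype", "size_class"])["total"].mean().items()
    }


def _default_type_fractions() -> np.ndarray:
    df = presets.mutation_table()
    totals = df[presets.MUTATION_TYPE_COLUMNS].sum(axis=0).to_numpy(dtype=float)
    return totals / totals.sum()


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and noise settings for synthetic data generation."""

    specs: dict[str, ModelSpec] = dc_field(default_factory=_default_specs)
    seed: int = 0
    # digestion stream
    digestion_n_per_age: dict[float, int] = dc_field(
        default_factory=lambda: {3.0: 3, 4.0: 4, 6.0: 4, 10.0: 4}
    )
    count_cv: float = 0.10
    # survey stream
    n_mice: int = 120
    survey_start_weeks: float = 10.0
    survey_end_weeks: float = 20.0
    survey_step_weeks: float = 0.5  # every 3.5 days
    cutoff_mm2: float = DEFAULT_CUTOFF_MM2
    s_area_min_mm2: float = 0.25
    l_area_log_scale: float = 0.8
    # palpation stream
    n_palpated_tumors: int = 90
    onset_age_mean_days: float = 113.0
    onset_age_sd_days: float = 15.0
    tvdt_mean_days: float = 12.0
    tvdt_cv: float = 0.2
    caliper_cv: float = 0.05
    detect_volume_mm3: float = 20.0
    endpoint_volume_mm3: float = 2000.0
    measurement_interval_days: float = 3.5
    # mutation stream
    mutation_means: dict[tuple[str, str], float] = dc_field(
        default_factory=_default_mutation_means
    )
    mutation_dispersion: float = 0.2  # NB alpha: var = mean + alpha * mean^2
    mutation_n_per_group: int = 3

    def __post_init__(self) -> None:
        if self.n_mice < 1 or self.survey_step_weeks <= 0:
            raise ValueError("n_mice must be >= 1 and survey step positive")
        if self.count_cv < 0 or self.caliper_cv < 0 or self.tvdt_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        if not 0 < self.s_area_min_mm2 < self.cutoff_mm2:
            raise ValueError("s_area_min_mm2 must lie in (0, cutoff)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])

    def survey_ages(self) -> np.ndarray:
        n = int(round((self.survey_end_weeks - self.survey_start_weeks)
                      / self.survey_step_weeks)) + 1
        return self.survey_start_weeks + self.survey_step_weeks * np.arange(n)


def _lognormal_factor(rng, cv: float, size=None):
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size)


def gen_digestion(config: CohortConfig) -> pd.DataFrame:
    """Gland-digestion counts (digestion.csv schema).

    One row per mouse x genotype; ``cell_count`` is the logistic field
    size at (age - 3) weeks times mean-one log-normal noise, and
    ``total_fluorescent`` sums the mouse's counts across genotypes.
    """
    rng = config.rng(_STREAM_DIGESTION)
    rows = []
    mouse_no = 0
    for age, n in sorted(config.digestion_n_per_age.items()):
        for _ in range(n):
            mouse_id = f"dig{mouse_no:03d}"
            mouse_no += 1
            counts = {}
            for g, spec in config.specs.items():
                mean = expected_counts(spec, [age])["F"][0]
                counts[g] = mean * _lognormal_factor(rng, config.count_cv)
            total = sum(counts.values())
            for g, c in counts.items():
                rows.append(
                    {
                        "mouse_id": mouse_id,
                        "age_weeks": age,
                        "genotype": g,
                        "cell_count": c,
                        "total_fluorescent": total,
                    }
                )
    return pd.DataFrame(rows)


def gen_survey(config: CohortConfig) -> SurveyCohort:
    """Cross-sectional necropsy survey as a :class:`SurveyCohort`.

    Mice are assigned sacrifice ages cycling through the survey grid;
    per mouse and genotype the S and L tumor counts are Poisson with the
    compartment-model means at that age.  Areas are drawn class-
    conditionally: S log-uniform on [s_area_min, cutoff), L log-normal
    shifted to lie at or above the cutoff — so the S/L classification is
    exact by construction.
    """
    rng = config.rng(_STREAM_SURVEY)
    ages_grid = config.survey_ages()
    mouse_ages = ages_grid[np.arange(config.n_mice) % ages_grid.size]

    means = {
        g: expected_counts(spec, mouse_ages) for g, spec in config.specs.items()
    }
    mice = pd.DataFrame(
        {"mouse_id": np.arange(config.n_mice), "age_weeks": mouse_ages}
    )
    tumor_rows = []
    for g in config.specs:
        s_counts = rng.poisson(means[g]["S"])
        l_counts = rng.poisson(means[g]["L"])
        for mid in range(config.n_mice):
            ns, nl = int(s_counts[mid]), int(l_counts[mid])
            if ns:
                areas = np.exp(
                    rng.uniform(
                        np.log(config.s_area_min_mm2),
                        np.log(config.cutoff_mm2),
                        size=ns,
                    )
                )
                for a in areas:
                    tumor_rows.append(
                        {"mouse_id": mid, "genotype": g, "area_mm2": float(a)}
                    )
            if nl:
                areas = config.cutoff_mm2 * np.exp(
                    rng.exponential(config.l_area_log_scale, size=nl)
                )
                for a in areas:
                    tumor_rows.append(
                        {"mouse_id": mid, "genotype": g, "area_mm2": float(a)}
                    )
    tumors = (
        pd.DataFrame(tumor_rows)
        if tumor_rows
        else pd.DataFrame({"mouse_id": [], "genotype": [], "area_mm2": []})
    )
    return SurveyCohort(mice=mice, tumors=tumors)


def gen_palpation(config: CohortConfig) -> list[PalpationSeries]:
    """Longitudinal palpation series with exponential tumor growth.

    Each tumor surfaces at the detection volume at a normally
    distributed onset age, doubles every TVDT_i days (TVDT_i normal
    around the configured mean, truncated positive), and is measured
    every 3.5 days with multiplicative caliper noise until its true
    volume reaches the burden endpoint.
    """
    rng = config.rng(_STREAM_PALPATION)
    genotypes = sorted(config.specs)
    series = []
    for i in range(config.n_palpated_tumors):
        g = genotypes[i % len(genotypes)]
        onset = rng.normal(config.onset_age_mean_days, config.onset_age_sd_days)
        dt = rng.normal(config.tvdt_mean_days, config.tvdt_cv * config.tvdt_mean_days)
        while dt <= 0:
            dt = rng.normal(
                config.tvdt_mean_days, config.tvdt_cv * config.tvdt_mean_days
            )
        ages, vols = [], []
        t = onset
        while True:
            true_v = config.detect_volume_mm3 * 2.0 ** ((t - onset) / dt)
            vols.append(true_v * _lognormal_factor(rng, config.caliper_cv))
            ages.append(t)
            if true_v >= config.endpoint_volume_mm3:
                break
            t += config.measurement_interval_days
        series.append(
            PalpationSeries(
                tumor_id=f"tum{i:03d}",
                genotype=g,
                age_days=np.array(ages),
                volume_mm3=np.array(vols),
            )
        )
    return series


def gen_mutation_table(config: CohortConfig) -> pd.DataFrame:
    """Per-tumor mutation counts (same layout as the published table).

    Totals are negative-binomial around the group mean with
    ``var = mean + alpha * mean^2`` (``alpha = mutation_dispersion``;
    alpha = 0 degenerates to Poisson); type counts are multinomial
    within each total, so total = sum of types holds by construction.
    """
    rng = config.rng(_STREAM_MUTATION)
    fractions = _default_type_fractions()
    rows = []
    for (g, s), mean in sorted(config.mutation_means.items()):
        for i in range(config.mutation_n_per_group):
            if mean == 0:
                total = 0
            elif config.mutation_dispersion == 0:
                total = int(rng.poisson(mean))
            else:
                k = 1.0 / config.mutation_dispersion
                total = int(rng.negative_binomial(k, k / (k + mean)))
            types = rng.multinomial(total, fractions)
            row = {"mouse": i + 1, "genotype": g, "size_class": s}
            row.update(dict(zip(presets.MUTATION_TYPE_COLUMNS, types.tolist())))
            row["total"] = total
            rows.append(row)
    return pd.DataFrame(rows)
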