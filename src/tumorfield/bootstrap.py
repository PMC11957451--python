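"""Hierarchical bootstrap for transition-rate uncertainty.

Each replicate (i) perturbs the fixed field parameters with a 5%-CV
normal jitter (redrawn if negative — they are physically non-negative),
(ii) resamples the cohort hierarchically: mice with replacement, then
tumors with replacement within each sampled mouse, restratified by
genotype and S/L state, (iii) jitters every synthetic mouse's age by a
0.05-week normal perturbation (applied only to the age used in the ODE
evaluation), and (iv) refits the transition rates.  Point estimates are
the per-parameter medians of the replicate draws; confidence intervals
are percentiles of the bootstrapped distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .data import DEFAULT_CUTOFF_MM2, SurveyCohort, state_counts
from .inference import FitResult, TransitionRateModel
from .models import FieldParams, TransitionRates, Variant

__all__ = ["BootstrapConfig", "BootstrapResult", "resample_cohort", "run_bootstrap"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for the hierarchical bootstrap."""

    n_reps: int = 1000
    seed: int = 0
    field_jitter_cv: float = 0.05
    age_jitter_sd: float = 0.05  # weeks
    ci_levels: tuple[float, ...] = (0.80, 0.90, 0.95)
    max_failure_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.field_jitter_cv < 0 or self.age_jitter_sd < 0:
            raise ValueError("jitter magnitudes must be >= 0")
        for lv in self.ci_levels:
            if not 0 < lv < 1:
                raise ValueError(f"ci level must be in (0, 1), got {lv}")


@dataclass
class BootstrapResult:
    """Replicate draws, medians and percentile intervals."""

    draws: pd.DataFrame  # one row per successful replicate, one column per rate
    medians: dict[str, float]
    intervals: dict[float, dict[str, tuple[float, float]]]
    n_failed_reps: int
    point_fit: FitResult

    @property
    def rates(self) -> TransitionRates:
        """Median-based point estimate as a TransitionRates object."""
        return TransitionRates(
            p1=self.medians["p1"],
            p2=self.medians["p2"],
            p0=self.medians.get("p0"),
        )

    def to_dict(self) -> dict:
        return {
            "medians": self.medians,
            "intervals": {
                str(lv): {k: list(v) for k, v in per.items()}
                for lv, per in self.intervals.items()
            },
            "n_reps": len(self.draws) + self.n_failed_reps,
            "n_failed_reps": self.n_failed_reps,
            "point_fit": self.point_fit.to_dict(),
        }


def resample_cohort(survey: SurveyCohort, rng: np.random.Generator) -> SurveyCohort:
    """One hierarchical resample: mice with replacement, then tumors
    with replacement within each sampled mouse.

    The synthetic cohort has exactly the same number of mice.  A mouse
    drawn k times contributes k independent synthetic mice, each with its
    own tumor resample; mice with zero tumors resample to zero tumors.
    """
    n = survey.n_mice
    if n == 0:
        raise ValueError("cannot resample an empty survey")
    picks = rng.integers(0, n, size=n)

    # plain-array lookup tables: mouse_id -> (genotype array, area array)
    by_mouse: dict = {}
    for mid, grp in survey.tumors.groupby("mouse_id", sort=False):
        by_mouse[mid] = (
            grp["genotype"].to_numpy(),
            grp["area_mm2"].to_numpy(dtype=float),
        )

    src_ids = survey.mice["mouse_id"].to_numpy()
    src_ages = survey.mice["age_weeks"].to_numpy(dtype=float)
    new_mouse_ids, genos, areas = [], [], []
    for new_id, idx in enumerate(picks):
        entry = by_mouse.get(src_ids[idx])
        if entry is not None:
            g, a = entry
            take = rng.integers(0, len(a), size=len(a))
            new_mouse_ids.append(np.full(len(a), new_id))
            genos.append(g[take])
            areas.append(a[take])
    if new_mouse_ids:
        tumors = pd.DataFrame(
            {
                "mouse_id": np.concatenate(new_mouse_ids),
                "genotype": np.concatenate(genos),
                "area_mm2": np.concatenate(areas),
            }
        )
    else:
        tumors = pd.DataFrame({"mouse_id": [], "genotype": [], "area_mm2": []})
    mice = pd.DataFrame(
        {"mouse_id": np.arange(n), "age_weeks": src_ages[picks]}
    )
    return SurveyCohort(mice=mice, tumors=tumors)


def _jitter_field(field: FieldParams, cv: float, rng: np.random.Generator) -> FieldParams:
    """Normal jitter with sd = cv * mean; negative draws are redrawn."""
    if cv == 0:
        return field
    vals = {}
    for name in ("r", "K", "F0"):
        mean = getattr(field, name)
        v = rng.normal(mean, cv * mean)
        while v <= 0:
            v = rng.normal(mean, cv * mean)
        vals[name] = v
    vals["F0"] = min(vals["F0"], vals["K"])
    return FieldParams(**vals)


def run_bootstrap(
    survey: SurveyCohort,
    field_fit: FitResult | FieldParams,
    variant: Variant | str = Variant.FSL,
    genotype: str = "",
    cutoff: float = DEFAULT_CUTOFF_MM2,
    config: BootstrapConfig = BootstrapConfig(),
    point_fit: FitResult | None = None,
) -> BootstrapResult:
    """Hierarchical bootstrap of the transition-rate fit for one genotype.

    ``field_fit`` supplies the preliminary OLS field estimate (either the
    FitResult or the FieldParams directly).  Replicate refits warm-start
    from the point fit; replicates whose refit fails are excluded and
    counted, and more than ``max_failure_fraction`` failures is an error.
    Deterministic given ``config.seed``.
    """
    field = field_fit.params if isinstance(field_fit, FitResult) else field_fit
    if isinstance(field_fit, FitResult) and not field_fit.converged:
        raise ValueError("field fit did not converge; refusing to bootstrap")
    variant = Variant(variant)

    if point_fit is None:
        model = TransitionRateModel(
            field=field, variant=variant, genotype_label=genotype, seed=config.seed
        )
        model.fit(state_counts(survey, genotype, cutoff))
        point_fit = model.result_
    x_point = np.array(list(point_fit.params.as_dict().values()))
    names = list(point_fit.params.as_dict())

    rng = np.random.default_rng(config.seed)
    draws = []
    n_failed = 0
    for _ in range(config.n_reps):
        fld = _jitter_field(field, config.field_jitter_cv, rng)
        boot = resample_cohort(survey, rng)
        counts = state_counts(boot, genotype, cutoff)
        if config.age_jitter_sd > 0:
            counts = counts.assign(
                age_weeks=counts["age_weeks"]
                + rng.normal(0.0, config.age_jitter_sd, size=len(counts))
            )
        try:
            rep = TransitionRateModel(
                field=fld, variant=variant, genotype_label=genotype
            ).fit(counts, x0=x_point)
            if not rep.result_.converged:
                raise RuntimeError(rep.result_.message)
            draws.append(rep.rates_.as_dict())
        except Exception:
            n_failed += 1
    if n_failed > config.max_failure_fraction * config.n_reps:
        raise RuntimeError(
            f"{n_failed}/{config.n_reps} bootstrap refits failed "
            f"(> {config.max_failure_fraction:.0%} allowed)"
        )

    draws_df = pd.DataFrame(draws, columns=names)
    medians = {k: float(draws_df[k].median()) for k in names}
    intervals: dict[float, dict[str, tuple[float, float]]] = {}
    for lv in config.ci_levels:
        alpha = (1.0 - lv) / 2.0
        intervals[lv] = {
            k: (
                float(draws_df[k].quantile(alpha)),
                float(draws_df[k].quantile(1.0 - alpha)),
            )
            for k in names
        }
    return BootstrapResult(
        draws=draws_df,
        medians=medians,
        intervals=intervals,
        n_failed_reps=n_failed,
        point_fit=point_fit,
    )
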