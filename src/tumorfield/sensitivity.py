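"""Morris elementary-effects screening of the compartment models.

One-at-a-time sensitivity screening over time: parameters are mapped to
the unit hypercube over their ranges, randomized Morris trajectories
perturb one parameter at a time on a level grid, and each step yields an
elementary effect

    EE_i(t) = |X(t; u + delta e_i) - X(t; u)| / |delta|

for the chosen output state X (F, O, S or L), with u in unit-cube
coordinates.  The screening statistic mu(t) is the mean absolute
elementary effect across trajectories — comparable across parameters of
very different scales because of the unit-cube normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .models import FieldParams, ModelSpec, TransitionRates, Variant, solve, SolverError

__all__ = [
    "MorrisConfig",
    "MorrisResult",
    "default_ranges",
    "elementary_effect",
    "morris_screen",
]


def default_ranges(spec: ModelSpec, rel: float = 0.5) -> dict[str, tuple[float, float]]:
    """Symmetric ranges (1 +/- rel) around the spec's parameter values."""
    vals = {
        "r": spec.field.r,
        "K": spec.field.K,
        "F0": spec.field.F0,
        **spec.rates.as_dict(),
    }
    return {k: (v * (1 - rel), v * (1 + rel)) for k, v in vals.items()}


@dataclass(frozen=True)
class MorrisConfig:
    """Design of a Morris screen."""

    param_ranges: dict[str, tuple[float, float]]
    t_grid: np.ndarray
    output_state: str = "L"
    n_trajectories: int = 100
    n_levels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trajectories < 2:
            raise ValueError("n_trajectories must be >= 2")
        if self.n_levels < 2 or self.n_levels % 2:
            raise ValueError("n_levels must be an even integer >= 2")
        for name, (lo, hi) in self.param_ranges.items():
            if not lo < hi:
                raise ValueError(
                    f"degenerate range for {name!r}: ({lo}, {hi}); lo < hi required"
                )


@dataclass
class MorrisResult:
    """mu(t) per parameter plus raw per-trajectory effects and ranking."""

    mu: pd.DataFrame  # index: time_weeks; columns: parameter names
    ee_raw: np.ndarray  # (n_trajectories, n_params, n_times) absolute effects
    ranking: list[str]  # parameters by decreasing mu at the final time

    def to_frame(self) -> pd.DataFrame:
        """Long-format (time_weeks, parameter, mu) export."""
        long = self.mu.reset_index().melt(
            id_vars="time_weeks", var_name="parameter", value_name="mu"
        )
        return long.sort_values(["parameter", "time_weeks"]).reset_index(drop=True)


def _apply_params(spec: ModelSpec, values: dict[str, float]) -> ModelSpec:
    """Rebuild a spec with the named parameters replaced."""
    fld = {
        "r": values.get("r", spec.field.r),
        "K": values.get("K", spec.field.K),
        "F0": values.get("F0", spec.field.F0),
    }
    fld["F0"] = min(fld["F0"], fld["K"])
    rates = spec.rates.as_dict()
    rates.update({k: v for k, v in values.items() if k in ("p0", "p1", "p2")})
    return ModelSpec(
        variant=spec.variant,
        field=FieldParams(**fld),
        rates=TransitionRates(
            p1=rates["p1"], p2=rates["p2"], p0=rates.get("p0")
        ),
        genotype_label=spec.genotype_label,
    )


def _output(spec: ModelSpec, t_grid, state: str) -> np.ndarray:
    return solve(spec, t_grid).state(state)


def elementary_effect(
    spec: ModelSpec,
    param_name: str,
    delta: float,
    t_grid,
    output_state: str = "L",
    param_ranges: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Elementary effect of one parameter on one output state over time.

    ``delta`` is the perturbation in unit-cube coordinates over the
    parameter's range; the base point is the spec's own value.  The
    perturbed value must stay inside the range.
    """
    if delta == 0:
        raise ValueError("delta must be nonzero")
    ranges = param_ranges or default_ranges(spec)
    lo, hi = ranges[param_name]
    vals = {
        "r": spec.field.r,
        "K": spec.field.K,
        "F0": spec.field.F0,
        **spec.rates.as_dict(),
    }
    u = (vals[param_name] - lo) / (hi - lo)
    u_new = u + delta
    if not (0.0 <= u_new <= 1.0):
        raise ValueError(
            f"perturbed {param_name} leaves its range: u={u:.3f} + delta={delta} "
            "falls outside [0, 1]"
        )
    t_grid = np.asarray(t_grid, dtype=float)
    base = _output(spec, t_grid, output_state)
    pert = _output(
        _apply_params(spec, {param_name: lo + u_new * (hi - lo)}), t_grid, output_state
    )
    return np.abs(pert - base) / abs(delta)


def morris_screen(spec: ModelSpec, config: MorrisConfig) -> MorrisResult:
    """Randomized one-at-a-time Morris screen; deterministic given seed.

    Base points sit on a ``n_levels`` grid in the unit hypercube; each
    trajectory perturbs every parameter exactly once (random order,
    random direction) by the standard step delta = p / (2 (p - 1)).
    Trajectories whose ODE solve fails are dropped with a warning.
    """
    # canonical (sorted) order so results are invariant to dict ordering
    names = sorted(config.param_ranges)
    for n in names:
        if n in ("p0", "p1", "p2") and n not in spec.rates.as_dict():
            raise ValueError(f"parameter {n!r} not present in variant {spec.variant.value}")
    t_grid = np.asarray(config.t_grid, dtype=float)
    p = config.n_levels
    delta = p / (2.0 * (p - 1.0))
    # base levels from which u + delta stays in [0, 1]
    base_levels = np.arange(0, p // 2) / (p - 1.0)
    rng = np.random.default_rng(config.seed)
    k = len(names)
    lo = np.array([config.param_ranges[n][0] for n in names])
    hi = np.array([config.param_ranges[n][1] for n in names])

    ee = np.full((config.n_trajectories, k, t_grid.size), np.nan)
    n_dropped = 0
    for traj in range(config.n_trajectories):
        u = base_levels[rng.integers(0, len(base_levels), size=k)].astype(float)
        direction = rng.choice([-1.0, 1.0], size=k)
        # flip any step that would leave the cube
        for i in range(k):
            if not (0.0 <= u[i] + direction[i] * delta <= 1.0):
                direction[i] = -direction[i]
        order = rng.permutation(k)
        try:
            current = _output(spec_at(spec, names, lo + u * (hi - lo)), t_grid,
                              config.output_state)
            for i in order:
                u[i] += direction[i] * delta
                nxt = _output(spec_at(spec, names, lo + u * (hi - lo)), t_grid,
                              config.output_state)
                ee[traj, i] = np.abs(nxt - current) / delta
                current = nxt
        except SolverError:  # pragma: no cover - defensive
            n_dropped += 1
            ee[traj] = np.nan
    if n_dropped:
        import warnings

        warnings.warn(f"dropped {n_dropped} Morris trajectories after solver failure")
    valid = ~np.isnan(ee[:, 0, 0])
    if valid.sum() < 2:
        raise RuntimeError("fewer than 2 valid Morris trajectories")
    mu = np.nanmean(ee[valid], axis=0)  # (k, n_times)
    mu_df = pd.DataFrame(mu.T, columns=names)
    mu_df.insert(0, "time_weeks", t_grid)
    mu_df = mu_df.set_index("time_weeks")
    ranking = list(mu_df.iloc[-1].sort_values(ascending=False).index)
    return MorrisResult(mu=mu_df, ee_raw=ee[valid], ranking=ranking)


def spec_at(spec: ModelSpec, names: list[str], values: np.ndarray) -> ModelSpec:
    """Spec with the named parameters set to the given natural values."""
    return _apply_params(spec, dict(zip(names, values)))
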