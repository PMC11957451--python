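"""Compartmental dynamics of field-driven mammary tumorigenesis.

Two nested dynamical systems describe tumor development in HER2-isoform
(d16 / p95) mouse mammary glands:

* **FSL** — a field of oncogene-transformed cells ``F`` grows logistically
  (rate ``r``, carrying capacity ``K``) and seeds small, screen-detectable
  lesions ``S`` at per-cell rate ``p1``; small lesions become large,
  palpable tumors ``L`` at per-lesion rate ``p2``.
* **FOSL** — inserts an *occult* dysplastic compartment ``O`` between the
  field and screen detection: ``F`` seeds ``O`` at per-cell rate ``p0``,
  occult lesions advance to ``S`` at per-lesion rate ``p1``, then to ``L``
  at ``p2``.

Time is measured in weeks since initiation; ``t = 0`` corresponds to an
age of 3 weeks (the earliest gland-digestion measurement).  The field is
not depleted by the transition terms: at fitted values the outflow
``p0*F`` (or ``p1*F``) is ~5 orders of magnitude below the logistic terms,
and ``F`` counts cells while ``O/S/L`` count lesions, so a unit-consistent
depletion term is ill-defined.  This is an explicit model assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Variant",
    "FieldParams",
    "TransitionRates",
    "ModelSpec",
    "StateTrajectory",
    "SolverError",
    "logistic_field",
    "rhs",
    "solve",
    "expected_counts",
]

_F0_TOL = 1e-9  # relative slack allowed for F0 above K
_ATOL = 1e-10  # absolute integration tolerance
_RTOL = 1e-8
_NEG_TOL = 1e-6  # tolerated negative excursion, lesions


class Variant(str, Enum):
    """Model variant: three-compartment FSL or four-compartment FOSL."""

    FSL = "FSL"
    FOSL = "FOSL"


class SolverError(RuntimeError):
    """Raised when the ODE integration fails or produces invalid states."""


@dataclass(frozen=True)
class FieldParams:
    """Logistic growth parameters of the transformed-cell field.

    Parameters
    ----------
    r : float
        Field replacement rate, per week.
    K : float
        Field carrying capacity, cells.
    F0 : float
        Field size at initiation (age 3 weeks), cells.
    """

    r: float
    K: float
    F0: float

    def __post_init__(self) -> None:
        if not (self.r >= 0):
            raise ValueError(f"field rate r must be >= 0, got {self.r}")
        if not (self.K > 0):
            raise ValueError(f"carrying capacity K must be > 0, got {self.K}")
        if not (0 < self.F0 <= self.K * (1 + _F0_TOL)):
            raise ValueError(
                f"initial field F0 must satisfy 0 < F0 <= K, got F0={self.F0}, K={self.K}"
            )


@dataclass(frozen=True)
class TransitionRates:
    """Compartment transition rates, per week.

    ``p0`` (field -> occult, per cell) is present only for the FOSL
    variant.  ``p1`` is field -> small (per cell) under FSL, or
    occult -> small (per lesion) under FOSL.  ``p2`` is small -> large,
    per lesion.
    """

    p1: float
    p2: float
    p0: float | None = None

    def __post_init__(self) -> None:
        for name in ("p0", "p1", "p2"):
            v = getattr(self, name)
            if v is not None and not (v >= 0):
                raise ValueError(f"transition rate {name} must be >= 0, got {v}")

    @property
    def variant(self) -> Variant:
        return Variant.FOSL if self.p0 is not None else Variant.FSL

    def as_dict(self) -> dict[str, float]:
        d = {"p1": self.p1, "p2": self.p2}
        if self.p0 is not None:
            d = {"p0": self.p0, **d}
        return d


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified dynamical system: variant + field + rates."""

    variant: Variant
    field: FieldParams
    rates: TransitionRates
    genotype_label: str = ""

    def __post_init__(self) -> None:
        v = Variant(self.variant)
        object.__setattr__(self, "variant", v)
        if self.rates.variant is not v:
            raise ValueError(
                f"rates structure {sorted(self.rates.as_dict())} does not match "
                f"variant {v.value}: FSL carries {{p1, p2}}, FOSL {{p0, p1, p2}}"
            )

    @property
    def n_states(self) -> int:
        return 4 if self.variant is Variant.FOSL else 3

    @property
    def state_names(self) -> tuple[str, ...]:
        return ("F", "O", "S", "L") if self.variant is Variant.FOSL else ("F", "S", "L")

    def initial_state(self) -> np.ndarray:
        """No pre-existing lesions at initiation: (F0, 0, 0[, 0])."""
        y0 = np.zeros(self.n_states)
        y0[0] = self.field.F0
        return y0

    def with_field(self, field: FieldParams) -> "ModelSpec":
        return replace(self, field=field)

    def with_rates(self, rates: TransitionRates) -> "ModelSpec":
        return replace(self, rates=rates)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.value,
            "genotype": self.genotype_label,
            "field": {"r": self.field.r, "K": self.field.K, "F0": self.field.F0},
            "rates": self.rates.as_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        rates = d["rates"]
        return cls(
            variant=Variant(d["variant"]),
            field=FieldParams(**d["field"]),
            rates=TransitionRates(
                p1=rates["p1"], p2=rates["p2"], p0=rates.get("p0")
            ),
            genotype_label=d.get("genotype", ""),
        )


@dataclass(frozen=True)
class StateTrajectory:
    """Solver output: compartment occupancies on a time grid.

    ``times`` are weeks since initiation (age 3 weeks maps to t=0).
    ``F`` is in cells; ``O`` (FOSL only), ``S`` and ``L`` are lesion counts.
    """

    times: np.ndarray
    F: np.ndarray
    S: np.ndarray
    L: np.ndarray
    O: np.ndarray | None = None

    def state(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise KeyError(f"state {name!r} not present in this trajectory")
        return arr

    def to_frame(self):
        import pandas as pd

        data = {"time_weeks": self.times, "F": self.F}
        if self.O is not None:
            data["O"] = self.O
        data["S"] = self.S
        data["L"] = self.L
        return pd.DataFrame(data)


def logistic_field(t, field: FieldParams):
    """Closed-form logistic field size F(t) at t weeks since initiation.

    F(t) = K*F0*e^{rt} / (K + F0*(e^{rt} - 1)), evaluated in the
    overflow-safe form K / (1 + (K/F0 - 1) e^{-rt}).  Vectorized over t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since initiation must be non-negative")
    out = field.K / (1.0 + (field.K / field.F0 - 1.0) * np.exp(-field.r * t))
    return out if out.ndim else float(out)


def rhs(state: Sequence[float], t: float, spec: ModelSpec) -> np.ndarray:
    """Right-hand side of the compartment ODEs at ``state`` and time ``t``.

    FSL:  dF = r F (1 - F/K);  dS = p1 F - p2 S;  dL = p2 S
    FOSL: dF = r F (1 - F/K);  dO = p0 F - p1 O;  dS = p1 O - p2 S;  dL = p2 S
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (spec.n_states,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({spec.n_states},) for "
            f"variant {spec.variant.value}"
        )
    f = spec.field
    p = spec.rates
    dF = f.r * state[0] * (1.0 - state[0] / f.K)
    if spec.variant is Variant.FOSL:
        F, O, S, _ = state
        return np.array([dF, p.p0 * F - p.p1 * O, p.p1 * O - p.p2 * S, p.p2 * S])
    F, S, _ = state
    return np.array([dF, p.p1 * F - p.p2 * S, p.p2 * S])


def _field_at(t: np.ndarray, field: FieldParams, f_init: float) -> np.ndarray:
    """Logistic field from an arbitrary start value (0 stays 0)."""
    if f_init == 0:
        return np.zeros_like(np.asarray(t, dtype=float))
    return field.K / (1.0 + (field.K / f_init - 1.0) * np.exp(-field.r * np.asarray(t, float)))


def solve(
    spec: ModelSpec,
    t_grid: Sequence[float],
    initial_state: Sequence[float] | None = None,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> StateTrajectory:
    """Integrate the compartment system on ``t_grid`` (weeks, increasing).

    The field equation is autonomous with a known closed form, so the
    system is solved by exact reduction: F(t) is evaluated analytically
    and drives the lesion compartments, which are integrated with a
    stiff-capable method (LSODA).  Small negative excursions (above
    ``-atol``) are clipped to zero; anything below is treated as a
    solver failure and raised as :class:`SolverError`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if np.any(t_grid < 0):
        raise ValueError("t_grid times must be >= 0 (weeks since initiation)")

    y0 = spec.initial_state() if initial_state is None else np.asarray(
        initial_state, dtype=float
    )
    if y0.shape != (spec.n_states,):
        raise ValueError(
            f"initial_state has shape {y0.shape}, expected ({spec.n_states},)"
        )
    if np.any(y0 < 0):
        raise ValueError("initial_state must be non-negative")

    f_init = float(y0[0])
    p = spec.rates
    fld = spec.field

    def lesion_rhs(t: float, y: np.ndarray) -> np.ndarray:
        F = _field_at(t, fld, f_init)
        if spec.variant is Variant.FOSL:
            O, S, _ = y
            return np.array([p.p0 * F - p.p1 * O, p.p1 * O - p.p2 * S, p.p2 * S])
        S, _ = y
        return np.array([p.p1 * F - p.p2 * S, p.p2 * S])

    # Solve from t=0 so callers can request grids not anchored at zero.
    t0 = 0.0
    t_end = float(t_grid[-1])
    if t_end == t0:
        ys_lesion = np.tile(y0[1:, None], (1, t_grid.size))
    else:
        sol = solve_ivp(
            lesion_rhs,
            (t0, t_end),
            y0[1:],
            method="LSODA",
            t_eval=t_grid,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverError(
                f"ODE integration failed for {spec.genotype_label or spec.variant.value}: "
                f"{sol.message} (t_span=({t0}, {t_end}), y0={y0.tolist()})"
            )
        ys_lesion = sol.y
    ys = np.vstack([_field_at(t_grid, fld, f_init), ys_lesion])
    if np.any(ys < -_NEG_TOL):
        worst = float(ys.min())
        raise SolverError(
            f"negative compartment excursion {worst:g} below -{_NEG_TOL:g}"
        )
    ys = np.clip(ys, 0.0, None)

    if spec.variant is Variant.FOSL:
        return StateTrajectory(times=t_grid, F=ys[0], O=ys[1], S=ys[2], L=ys[3])
    return StateTrajectory(times=t_grid, F=ys[0], S=ys[1], L=ys[2])


AGE_AT_INITIATION_WEEKS = 3.0


def expected_counts(spec: ModelSpec, ages):
    """Expected per-mouse compartment counts at the given ages (weeks).

    Maps age ``a`` to model time ``t = a - 3`` and returns a dict of
    arrays keyed by state name ("S", "L" and, under FOSL, "O"), aligned
    to ``ages``.  Ages may be unsorted or contain duplicates.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if np.any(ages < AGE_AT_INITIATION_WEEKS):
        raise ValueError("ages must be >= 3 weeks (the initiation age)")
    t = ages - AGE_AT_INITIATION_WEEKS
    t_unique, inverse = np.unique(t, return_inverse=True)
    traj = solve(spec, t_unique)
    out = {"S": traj.S[inverse], "L": traj.L[inverse]}
    if spec.variant is Variant.FOSL:
        out["O"] = traj.O[inverse]
    out["F"] = traj.F[inverse]
    return out
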