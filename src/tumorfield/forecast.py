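"""Lifetime tumor-risk simulation over initiation age and field size.

Forward-simulates the three-compartment (FSL) chain from a chosen
initiation age to the end of a mouse's expected lifespan (2 years = 104
weeks), with the field held constant at a prescribed size: K is set to
the field size and r's contribution nulled, so field growth plays no
part.  The output is the expected number of large, palpable tumors
``E[L]`` at the horizon, classified by the legend thresholds: < 0.5 low,
0.5–1 an increasing gradient of risk, >= 1 one or more expected tumors.
``E[L]`` is the default risk measure; the Poisson transform
``P(at least one tumor) = 1 - exp(-E[L])`` is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .models import FieldParams, ModelSpec, TransitionRates, Variant, solve

__all__ = ["RiskClass", "RiskGrid", "simulate_lifetime", "build_grid"]

LIFESPAN_WEEKS = 104.0  # 2 years, the expected lifespan of a captive mouse


class RiskClass(str, Enum):
    LOW = "low"
    GRADIENT = "gradient"
    ONE_OR_MORE = "one_or_more"


def classify_risk(expected_l: float) -> RiskClass:
    if expected_l >= 1.0:
        return RiskClass.ONE_OR_MORE
    if expected_l >= 0.5:
        return RiskClass.GRADIENT
    return RiskClass.LOW


def simulate_lifetime(
    spec: ModelSpec,
    initiation_age: float,
    field_size: float,
    horizon: float = LIFESPAN_WEEKS,
) -> float:
    """Expected number of palpable tumors at ``horizon`` weeks of age.

    The FSL chain is integrated from ``initiation_age`` to ``horizon``
    with the field frozen at ``field_size`` cells (r = 0, F0 = K = field
    size).  Rates are taken from ``spec``; a FOSL spec contributes its
    p1/p2 (the occult inflow p0 is not part of this projection, which
    uses the three-compartment model).
    """
    if not horizon > initiation_age:
        raise ValueError(
            f"horizon ({horizon} wk) must exceed initiation age ({initiation_age} wk)"
        )
    if field_size < 0:
        raise ValueError("field_size must be >= 0")
    if field_size == 0:
        return 0.0
    frozen = ModelSpec(
        variant=Variant.FSL,
        field=FieldParams(r=0.0, K=field_size, F0=field_size),
        rates=TransitionRates(p1=spec.rates.p1, p2=spec.rates.p2),
        genotype_label=spec.genotype_label,
    )
    span = horizon - initiation_age
    traj = solve(frozen, np.array([span]))
    return float(traj.L[-1])


@dataclass
class RiskGrid:
    """Expected palpable-tumor counts over an age x field-size grid."""

    initiation_ages: np.ndarray  # weeks
    field_sizes: np.ndarray  # cells
    expected_L: np.ndarray  # shape (n_sizes, n_ages)
    risk_class: np.ndarray  # same shape, RiskClass values
    genotype_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, n in enumerate(self.field_sizes):
            for j, a in enumerate(self.initiation_ages):
                rows.append(
                    {
                        "initiation_age_weeks": a,
                        "field_size_cells": n,
                        "expected_L": self.expected_L[i, j],
                        "class": RiskClass(self.risk_class[i, j]).value,
                    }
                )
        return pd.DataFrame(rows)

    def minimal_field_size(
        self, risk_class: RiskClass = RiskClass.GRADIENT
    ) -> np.ndarray:
        """Per initiation age, the smallest grid field size reaching at
        least the given class (NaN if none does)."""
        threshold = 0.5 if risk_class is RiskClass.GRADIENT else 1.0
        out = np.full(self.initiation_ages.size, np.nan)
        for j in range(self.initiation_ages.size):
            hits = np.nonzero(self.expected_L[:, j] >= threshold)[0]
            if hits.size:
                out[j] = self.field_sizes[hits[0]]
        return out

    def plot(self, ax=None):
        """Render the grid as a heatmap (green / red gradient / dark red)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.colors import BoundaryNorm, ListedColormap

        if ax is None:
            _, ax = plt.subplots()
        cmap = ListedColormap(["#2ca02c", "#ff9896", "#8b0000"])
        norm = BoundaryNorm([0.0, 0.5, 1.0, np.inf], cmap.N)
        ax.pcolormesh(
            self.initiation_ages, self.field_sizes, self.expected_L, cmap=cmap,
            norm=norm, shading="nearest",
        )
        ax.set_xlabel("initiation age (weeks)")
        ax.set_ylabel("field size (cells)")
        ax.set_title(f"expected palpable tumors by {LIFESPAN_WEEKS:.0f} wk "
                     f"{self.genotype_label}".strip())
        return ax


def build_grid(
    spec: ModelSpec,
    ages,
    sizes,
    horizon: float = LIFESPAN_WEEKS,
    poisson_transform: bool = False,
) -> RiskGrid:
    """Evaluate ``simulate_lifetime`` over an initiation-age x size grid.

    With ``poisson_transform`` the classified quantity is
    ``1 - exp(-E[L])`` (probability of at least one tumor) instead of the
    expectation itself; ``expected_L`` always stores E[L].
    """
    ages = np.asarray(ages, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if ages.size == 0 or sizes.size == 0:
        raise ValueError("grid axes must be non-empty")
    expected = np.empty((sizes.size, ages.size))
    # E[L] is exactly linear in the frozen field size, so one simulation
    # per age at unit size scales to every row.
    for j, a in enumerate(ages):
        per_cell = simulate_lifetime(spec, a, 1.0, horizon)
        expected[:, j] = per_cell * sizes
    measure = 1.0 - np.exp(-expected) if poisson_transform else expected
    classes = np.empty(expected.shape, dtype=object)
    for idx in np.ndindex(expected.shape):
        classes[idx] = classify_risk(measure[idx])
    return RiskGrid(
        initiation_ages=ages,
        field_sizes=sizes,
        expected_L=expected,
        risk_class=classes,
        genotype_label=spec.genotype_label,
    )
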