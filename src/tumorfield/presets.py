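"""Reference parameter estimates and data tables for the HBOW HER2 models.

These are the published point estimates for the d16 and p95 HER2-isoform
field-to-tumor models (logistic field parameters estimated from gland
digestion counts; transition rates from a 120-mouse cross-sectional
necropsy survey, with 95% bootstrap confidence intervals), plus the
whole-exome mutation-count table for the sequenced tumors.  They serve as
generator inputs for synthetic cohorts and as worked-example constants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import FieldParams, ModelSpec, TransitionRates, Variant

__all__ = [
    "field_params",
    "fsl_spec",
    "fosl_spec",
    "FSL_CI95",
    "FOSL_CI95",
    "mutation_table",
]

# Logistic field parameters per genotype (shared by FSL and FOSL fits).
_FIELD = {
    "d16": FieldParams(r=0.7313, K=233_000.0, F0=26_000.0),
    "p95": FieldParams(r=0.1346, K=26_000.0, F0=12_000.0),
}

# Three-compartment (FSL) transition rates, per week.
_FSL_RATES = {
    "d16": TransitionRates(p1=3.259e-6, p2=0.0229),
    "p95": TransitionRates(p1=3.048e-5, p2=0.0405),
}

# 95% bootstrap confidence intervals for the FSL rates.
FSL_CI95 = {
    "d16": {"p1": (2.786e-6, 3.846e-6), "p2": (0.0148, 0.0315)},
    "p95": {"p1": (2.544e-5, 3.599e-5), "p2": (0.0321, 0.0502)},
}

# Four-compartment (FOSL) transition rates, by palpable-size cutoff (mm^2).
_FOSL_RATES = {
    9.0: {
        "d16": TransitionRates(p0=3.40e-6, p1=10.4332, p2=0.0237),
        "p95": TransitionRates(p0=3.20e-5, p1=5.6362, p2=0.0426),
    },
    1.5: {
        "d16": TransitionRates(p0=3.38e-6, p1=8.2566, p2=0.0764),
        "p95": TransitionRates(p0=3.21e-5, p1=4.7475, p2=0.1258),
    },
}

FOSL_CI95 = {
    9.0: {
        "d16": {
            "p0": (2.870e-6, 4.339e-6),
            "p1": (0.4220, 65.5811),
            "p2": (0.0178, 0.0310),
        },
        "p95": {
            "p0": (2.652e-5, 4.952e-5),
            "p1": (0.2117, 15.5382),
            "p2": (0.0348, 0.0522),
        },
    },
    1.5: {
        "d16": {
            "p0": (2.861e-6, 6.940e-6),
            "p1": (0.1101, 99.8215),
            "p2": (0.0614, 0.0981),
        },
        "p95": {
            "p0": (2.632e-5, 5.079e-5),
            "p1": (0.2064, 17.1339),
            "p2": (0.1051, 0.1586),
        },
    },
}


def field_params(genotype: str) -> FieldParams:
    """Published logistic field parameters for ``genotype`` ("d16" or "p95")."""
    return _FIELD[genotype]


def fsl_spec(genotype: str) -> ModelSpec:
    """Published three-compartment (FSL) model for ``genotype``."""
    return ModelSpec(
        variant=Variant.FSL,
        field=_FIELD[genotype],
        rates=_FSL_RATES[genotype],
        genotype_label=genotype,
    )


def fosl_spec(genotype: str, cutoff_mm2: float = 9.0) -> ModelSpec:
    """Published four-compartment (FOSL) model at the given size cutoff."""
    return ModelSpec(
        variant=Variant.FOSL,
        field=_FIELD[genotype],
        rates=_FOSL_RATES[float(cutoff_mm2)][genotype],
        genotype_label=genotype,
    )


# Whole-exome mutation counts per sequenced tumor: non-synonymous exonic
# mutations by type, for d16/p95 tumors classified palpable or unpalpable.
_MUTATION_ROWS = [
    # mouse, genotype, size_class, missense, nonsense, start_codon,
    #   start_loss, stop_loss, frameshift, in_frame, total
    (1, "d16", "palpable", 3830, 610, 0, 10, 4, 5, 0, 4459),
    (1, "d16", "palpable", 2631, 254, 0, 4, 0, 5, 1, 2895),
    (1, "d16", "unpalpable", 3443, 259, 0, 3, 1, 3, 1, 3710),
    (1, "p95", "unpalpable", 4580, 390, 0, 12, 1, 3, 0, 4986),
    (1, "p95", "unpalpable", 4493, 440, 0, 11, 0, 6, 1, 4951),
    (2, "d16", "palpable", 950, 69, 0, 2, 1, 1, 0, 1023),
    (2, "d16", "unpalpable", 6184, 617, 0, 13, 2, 1, 0, 6817),
    (2, "d16", "unpalpable", 10878, 857, 2, 20, 3, 5, 0, 11765),
    (2, "p95", "palpable", 4090, 306, 0, 9, 3, 1, 0, 4409),
    (2, "p95", "palpable", 1347, 115, 1, 1, 0, 1, 0, 1465),
    (2, "p95", "unpalpable", 2856, 244, 0, 6, 2, 1, 0, 3109),
]

MUTATION_TYPE_COLUMNS = [
    "missense",
    "nonsense",
    "start_codon",
    "start_loss",
    "stop_loss",
    "frameshift",
    "in_frame",
]


def mutation_table() -> pd.DataFrame:
    """Published per-tumor mutation counts as a validated DataFrame."""
    df = pd.DataFrame(
        _MUTATION_ROWS,
        columns=["mouse", "genotype", "size_class"] + MUTATION_TYPE_COLUMNS + ["total"],
    )
    assert (df[MUTATION_TYPE_COLUMNS].sum(axis=1) == df["total"]).all()
    return df
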