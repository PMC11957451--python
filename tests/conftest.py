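import numpy as np
import pytest

from tumorfield import CohortConfig, gen_survey, presets
from tumorfield.models import FieldParams, ModelSpec, TransitionRates, Variant


@pytest.fixture(scope="session")
def d16_fsl() -> ModelSpec:
    return presets.fsl_spec("d16")


@pytest.fixture(scope="session")
def p95_fsl() -> ModelSpec:
    return presets.fsl_spec("p95")


@pytest.fixture(scope="session")
def d16_fosl() -> ModelSpec:
    return presets.fosl_spec("d16")


@pytest.fixture(scope="session")
def p95_fosl() -> ModelSpec:
    return presets.fosl_spec("p95")


@pytest.fixture(scope="session")
def small_survey():
    """A 60-mouse FSL survey used by tests that only need plausible data."""
    return gen_survey(CohortConfig(seed=42, n_mice=60))


def rk4_solve(spec: ModelSpec, t_end: float, dt: float = 1e-3) -> np.ndarray:
    """Independent fixed-step RK4 integration of the full coupled system.

    Deliberately naive (no reuse of the package's solver machinery): the
    derivative is recomputed from the printed equations here.
    """

    def deriv(y):
        f = spec.field
        p = spec.rates
        dF = f.r * y[0] * (1.0 - y[0] / f.K)
        if spec.variant is Variant.FOSL:
            return np.array(
                [
                    dF,
                    p.p0 * y[0] - p.p1 * y[1],
                    p.p1 * y[1] - p.p2 * y[2],
                    p.p2 * y[2],
                ]
            )
        return np.array([dF, p.p1 * y[0] - p.p2 * y[1], p.p2 * y[1]])

    n = int(round(t_end / dt))
    y = spec.initial_state().astype(float)
    for _ in range(n):
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y
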