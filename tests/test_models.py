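"""Core dynamical-system tests: closed forms, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorfield import (
    FieldParams,
    ModelSpec,
    TransitionRates,
    Variant,
    expected_counts,
    logistic_field,
    rhs,
    solve,
)
from tumorfield.models import SolverError

from conftest import rk4_solve


class TestLogisticField:
    def test_initial_condition(self, d16_fsl):
        assert logistic_field(0.0, d16_fsl.field) == pytest.approx(26_000.0)

    def test_saturates_at_carrying_capacity(self, d16_fsl):
        assert logistic_field(1e4, d16_fsl.field) == pytest.approx(
            233_000.0, rel=1e-6
        )

    def test_zero_rate_is_constant(self):
        fp = FieldParams(r=0.0, K=1e5, F0=1234.0)
        t = np.linspace(0, 50, 7)
        np.testing.assert_allclose(logistic_field(t, fp), 1234.0)

    def test_negative_time_rejected(self, d16_fsl):
        with pytest.raises(ValueError):
            logistic_field(-0.1, d16_fsl.field)

    def test_matches_numeric_integration_of_logistic_ode(self, p95_fsl):
        # dF/dt = r F (1 - F/K) integrated by quadrature-free RK4
        fp = p95_fsl.field
        dt, t_end = 1e-4, 10.0
        f = fp.F0
        for _ in range(int(t_end / dt)):
            k1 = fp.r * f * (1 - f / fp.K)
            fm = f + 0.5 * dt * k1
            k2 = fp.r * fm * (1 - fm / fp.K)
            fm = f + 0.5 * dt * k2
            k3 = fp.r * fm * (1 - fm / fp.K)
            fe = f + dt * k3
            k4 = fp.r * fe * (1 - fe / fp.K)
            f += (dt / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        assert logistic_field(t_end, fp) == pytest.approx(f, rel=1e-8)


class TestRhs:
    def test_fixed_point_at_carrying_capacity(self):
        spec = ModelSpec(
            Variant.FSL,
            FieldParams(r=0.5, K=1e5, F0=1e5),
            TransitionRates(p1=0.0, p2=0.0),
        )
        np.testing.assert_allclose(rhs([1e5, 0.0, 0.0], 0.0, spec), 0.0)

    def test_pure_decay_when_inflow_off(self):
        spec = ModelSpec(
            Variant.FSL,
            FieldParams(r=0.5, K=1e5, F0=1e4),
            TransitionRates(p1=0.0, p2=0.1),
        )
        d = rhs([1e4, 5.0, 0.0], 0.0, spec)
        assert d[1] == pytest.approx(-0.1 * 5.0)

    def test_palpable_inflow_at_published_rate(self, d16_fsl):
        d = rhs([233_000.0, 10.0, 0.0], 0.0, d16_fsl)
        assert d[2] == pytest.approx(0.0229 * 10.0)

    def test_state_shape_mismatch_rejected(self, d16_fsl, d16_fosl):
        with pytest.raises(ValueError):
            rhs([1.0, 2.0, 3.0, 4.0], 0.0, d16_fsl)
        with pytest.raises(ValueError):
            rhs([1.0, 2.0, 3.0], 0.0, d16_fosl)

    def test_fosl_outflow_accounting(self, p95_fosl):
        # d(O+S+L)/dt = p0 * F
        y = np.array([20_000.0, 3.0, 2.0, 1.0])
        d = rhs(y, 0.0, p95_fosl)
        assert d[1:].sum() == pytest.approx(p95_fosl.rates.p0 * y[0])


class TestSolve:
    def test_constant_trajectory_at_fixed_point(self):
        spec = ModelSpec(
            Variant.FSL,
            FieldParams(r=0.5, K=1e5, F0=1e5),
            TransitionRates(p1=0.0, p2=0.0),
        )
        traj = solve(spec, np.linspace(0, 20, 11))
        np.testing.assert_allclose(traj.F, 1e5, rtol=1e-9)
        np.testing.assert_allclose(traj.S, 0.0)
        np.testing.assert_allclose(traj.L, 0.0)

    def test_constant_field_closed_form(self):
        # r=0, F0=K: S(t) = (p1 K / p2)(1 - e^{-p2 t})
        K, p1, p2 = 1e4, 1e-5, 0.05
        spec = ModelSpec(
            Variant.FSL, FieldParams(r=0.0, K=K, F0=K), TransitionRates(p1=p1, p2=p2)
        )
        t = np.linspace(0.5, 17, 34)
        traj = solve(spec, t)
        expected = (p1 * K / p2) * (1 - np.exp(-p2 * t))
        np.testing.assert_allclose(traj.S, expected, rtol=1e-6)

    def test_matches_independent_rk4_oracle(self, d16_fsl):
        y_ref = rk4_solve(d16_fsl, t_end=17.0, dt=1e-3)
        traj = solve(d16_fsl, np.array([17.0]))
        assert traj.S[-1] == pytest.approx(y_ref[1], rel=1e-6)
        assert traj.L[-1] == pytest.approx(y_ref[2], rel=1e-6)

    def test_fosl_matches_rk4_oracle(self, p95_fosl):
        y_ref = rk4_solve(p95_fosl, t_end=17.0, dt=1e-3)
        traj = solve(p95_fosl, np.array([17.0]))
        assert traj.O[-1] == pytest.approx(y_ref[1], rel=1e-6)
        assert traj.S[-1] == pytest.approx(y_ref[2], rel=1e-6)
        assert traj.L[-1] == pytest.approx(y_ref[3], rel=1e-6)

    def test_non_increasing_grid_rejected(self, d16_fsl):
        with pytest.raises(ValueError):
            solve(d16_fsl, np.array([0.0, 2.0, 1.0]))

    def test_negative_initial_state_rejected(self, d16_fsl):
        with pytest.raises(ValueError):
            solve(d16_fsl, np.array([1.0]), initial_state=[-1.0, 0.0, 0.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        r=st.floats(0.0, 2.0),
        k_log=st.floats(3.0, 6.0),
        f0_frac=st.floats(1e-3, 1.0),
        p1_log=st.floats(-7.0, -3.0),
        p2_log=st.floats(-3.0, 0.0),
    )
    def test_nonnegativity_and_monotone_L_over_parameter_sweep(
        self, r, k_log, f0_frac, p1_log, p2_log
    ):
        K = 10.0**k_log
        spec = ModelSpec(
            Variant.FSL,
            FieldParams(r=r, K=K, F0=f0_frac * K),
            TransitionRates(p1=10.0**p1_log, p2=10.0**p2_log),
        )
        traj = solve(spec, np.linspace(0, 17, 18))
        for arr in (traj.F, traj.S, traj.L):
            assert np.all(arr >= 0)
        assert np.all(np.diff(traj.L) >= -1e-9 * (1 + traj.L[-1]))
        assert np.all(traj.F <= max(spec.field.F0, K) * (1 + 1e-6))

    def test_fosl_converges_to_fsl_when_occult_transit_is_fast(self, d16_fsl):
        # p1 -> infinity with p0 fixed collapses O: FOSL -> FSL with p1 := p0
        fosl = ModelSpec(
            Variant.FOSL,
            d16_fsl.field,
            TransitionRates(
                p0=d16_fsl.rates.p1, p1=1e4, p2=d16_fsl.rates.p2
            ),
        )
        t = np.linspace(1.0, 17.0, 17)
        a, b = solve(fosl, t), solve(d16_fsl, t)
        np.testing.assert_allclose(a.S, b.S, rtol=0.01)
        np.testing.assert_allclose(a.L, b.L, rtol=0.01)


class TestExpectedCounts:
    def test_zero_at_initiation_age(self, d16_fsl):
        out = expected_counts(d16_fsl, [3.0])
        assert out["S"][0] == 0.0 and out["L"][0] == 0.0

    def test_age_below_initiation_rejected(self, d16_fsl):
        with pytest.raises(ValueError):
            expected_counts(d16_fsl, [2.5])

    def test_palpable_expectation_nondecreasing_in_age(self, p95_fsl):
        ages = np.linspace(3, 25, 23)
        out = expected_counts(p95_fsl, ages)
        assert np.all(np.diff(out["L"]) >= 0)

    def test_genotype_ordering_and_oracle_magnitudes_at_week_20(
        self, d16_fsl, p95_fsl
    ):
        s = {
            spec.genotype_label: expected_counts(spec, [20.0])["S"][0]
            for spec in (d16_fsl, p95_fsl)
        }
        assert s["d16"] > s["p95"]
        for spec in (d16_fsl, p95_fsl):
            ref = rk4_solve(spec, t_end=17.0, dt=1e-3)
            assert expected_counts(spec, [20.0])["S"][0] == pytest.approx(
                ref[1], rel=1e-6
            )

    def test_unsorted_and_duplicate_ages_align(self, d16_fsl):
        out = expected_counts(d16_fsl, [15.0, 10.0, 15.0])
        assert out["S"][0] == out["S"][2]
        assert out["S"][1] < out["S"][0]


class TestSpecStructure:
    def test_variant_rate_mismatch_rejected(self, d16_fsl):
        with pytest.raises(ValueError):
            ModelSpec(
                Variant.FOSL, d16_fsl.field, TransitionRates(p1=1e-6, p2=0.02)
            )
        with pytest.raises(ValueError):
            ModelSpec(
                Variant.FSL,
                d16_fsl.field,
                TransitionRates(p0=1e-6, p1=1.0, p2=0.02),
            )

    def test_f0_above_k_rejected(self):
        with pytest.raises(ValueError):
            FieldParams(r=0.5, K=1e4, F0=2e4)

    def test_json_round_trip(self, p95_fosl):
        again = ModelSpec.from_dict(p95_fosl.to_dict())
        assert again == p95_fosl
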