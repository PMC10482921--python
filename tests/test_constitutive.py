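"""PTT constitutive model: destruction function, stress evolution,
steady-shear oracle, and structural invariants."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emboclot.constitutive import (
    EXP_ARG_CAP,
    KinematicsHistory,
    PTTParameters,
    StressHistory,
    SymmetricStressTensor,
    breakage_factor,
    fiber_strain,
    integrate_stress,
    steady_simple_shear,
    stress_rate,
)

P_REF = PTTParameters(eta_p=2.1e4, lambda_relax=6.0, epsilon=0.01)


class TestParameters:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"eta_p": -1.0, "lambda_relax": 1.0},
            {"eta_p": 1.0, "lambda_relax": 0.0},
            {"eta_p": 1.0, "lambda_relax": 1.0, "epsilon": -0.1},
            {"eta_p": float("nan"), "lambda_relax": 1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PTTParameters(**kwargs)

    def test_modulus_and_json_roundtrip(self):
        assert P_REF.modulus == pytest.approx(3500.0)
        assert PTTParameters.from_json_dict(P_REF.to_json_dict()) == P_REF


class TestBreakageFactor:
    @pytest.mark.parametrize(
        "trace, expected",
        [
            (0.0, 1.0),
            # eps*lam/eta_p * 3500 = 0.01 for the reference parameters
            (3500.0, math.exp(0.01)),
            # trace giving fiber strain 10
            (10.0 * P_REF.eta_p / P_REF.lambda_relax, math.exp(0.1)),
        ],
    )
    def test_values(self, trace, expected):
        assert breakage_factor(P_REF, trace) == pytest.approx(expected, rel=1e-12)
        tau = SymmetricStressTensor(xx=trace / 3, yy=trace / 3, zz=trace / 3)
        assert breakage_factor(P_REF, tau) == pytest.approx(expected, rel=1e-12)

    def test_argument_cap_logged(self, caplog):
        huge = 100.0 * P_REF.eta_p / (P_REF.epsilon * P_REF.lambda_relax)
        with caplog.at_level(logging.WARNING, logger="emboclot.constitutive"):
            value = breakage_factor(P_REF, huge)
        assert value == pytest.approx(math.exp(EXP_ARG_CAP))
        assert any("cap" in rec.message for rec in caplog.records)

    @given(
        tr_lo=st.floats(0.0, 1e5),
        tr_hi=st.floats(0.0, 1e5),
    )
    def test_monotone_in_trace(self, tr_lo, tr_hi):
        lo, hi = sorted([tr_lo, tr_hi])
        assert breakage_factor(P_REF, lo) <= breakage_factor(P_REF, hi)


class TestFiberStrain:
    @pytest.mark.parametrize(
        "trace, expected",
        [
            (0.0, 0.0),
            (P_REF.eta_p / P_REF.lambda_relax, 1.0),
            (3500.0, 1.0),  # 6 * 3500 / 21000
        ],
    )
    def test_values(self, trace, expected):
        assert fiber_strain(P_REF, trace) == pytest.approx(expected)


class TestStressRate:
    def test_zero_state_zero_kinematics(self):
        rate = stress_rate(P_REF, SymmetricStressTensor.zero(), np.zeros((3, 3)))
        assert np.allclose(rate.as_vector(), 0.0)

    def test_startup_of_shear_from_rest(self):
        gamma_dot = 2.0
        g = KinematicsHistory.simple_shear(gamma_dot).grad_u(0.0)
        rate = stress_rate(P_REF, SymmetricStressTensor.zero(), g)
        assert rate.xy == pytest.approx(P_REF.eta_p * gamma_dot / P_REF.lambda_relax)
        assert rate.xx == rate.yy == rate.zz == 0.0
        # symmetric by construction
        m = rate.as_matrix()
        assert np.array_equal(m, m.T)

    def test_pure_relaxation_linearization(self):
        tau = SymmetricStressTensor(xx=1.0, yy=0.5, xy=0.2)
        rate = stress_rate(P_REF, tau, np.zeros((3, 3)))
        expected = -tau.as_vector() / P_REF.lambda_relax
        assert np.allclose(rate.as_vector(), expected, rtol=1e-4)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            stress_rate(P_REF, SymmetricStressTensor.zero(), np.full((3, 3), np.nan))
        with pytest.raises(ValueError):
            stress_rate(P_REF, SymmetricStressTensor(xx=np.inf), np.zeros((3, 3)))


class TestIntegration:
    def test_pure_relaxation_matches_closed_form(self):
        """Small-stress relaxation follows tau0 * exp(-t/lambda)."""
        tau0 = SymmetricStressTensor(xx=10.0, yy=5.0, xy=2.0)
        hist = integrate_stress(
            P_REF, KinematicsHistory.rest(), (0.0, P_REF.lambda_relax), tau0
        )
        expected = tau0.as_vector() * math.exp(-1.0)
        nz = expected != 0.0
        rel = np.abs(hist.final.as_vector()[nz] - expected[nz]) / np.abs(expected[nz])
        assert rel.max() < 1e-3

    @pytest.mark.parametrize("weissenberg", [0.01, 0.1, 1.0, 10.0])
    def test_long_time_limit_matches_algebraic_steady_state(self, weissenberg):
        gamma_dot = weissenberg / P_REF.lambda_relax
        oracle = steady_simple_shear(P_REF, gamma_dot)
        hist = integrate_stress(
            P_REF,
            KinematicsHistory.simple_shear(gamma_dot),
            (0.0, 40.0 * P_REF.lambda_relax),
        )
        num = np.linalg.norm(hist.final.as_vector() - oracle.as_vector())
        assert num / np.linalg.norm(oracle.as_vector()) < 1e-6

    def test_newtonian_limit_of_slow_shear(self):
        """For Wi << 1 the long-time shear stress is eta_p * gamma_dot."""
        gamma_dot = 0.01 / P_REF.lambda_relax
        hist = integrate_stress(
            P_REF,
            KinematicsHistory.simple_shear(gamma_dot),
            (0.0, 20.0 * P_REF.lambda_relax),
        )
        assert hist.final.xy == pytest.approx(P_REF.eta_p * gamma_dot, rel=0.01)

    def test_self_convergence_on_tolerance_halving(self):
        gamma_dot = 1.0 / P_REF.lambda_relax
        kin = KinematicsHistory.simple_shear(gamma_dot)
        span = (0.0, 3.0 * P_REF.lambda_relax)
        tol = 1e-6
        a = integrate_stress(P_REF, kin, span, tol=tol).final.as_vector()
        b = integrate_stress(P_REF, kin, span, tol=tol / 2).final.as_vector()
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < tol

    def test_invalid_span_and_tolerance(self):
        with pytest.raises(ValueError):
            integrate_stress(P_REF, KinematicsHistory.rest(), (1.0, 0.0))
        with pytest.raises(ValueError):
            integrate_stress(P_REF, KinematicsHistory.rest(), (0.0, 1.0), tol=0.0)

    @given(scale=st.floats(0.5, 4.0))
    def test_linearity_in_eta_p_at_small_strain(self, scale):
        """Doubling eta_p at fixed lambda doubles the small-strain
        stress response to identical kinematics."""
        gamma_dot = 0.001 / P_REF.lambda_relax  # fiber strain stays tiny
        kin = KinematicsHistory.simple_shear(gamma_dot)
        span = (0.0, 2.0 * P_REF.lambda_relax)
        base = integrate_stress(P_REF, kin, span).final.xy
        scaled_params = PTTParameters(
            eta_p=scale * P_REF.eta_p, lambda_relax=P_REF.lambda_relax,
            epsilon=P_REF.epsilon,
        )
        scaled = integrate_stress(scaled_params, kin, span).final.xy
        assert scaled == pytest.approx(scale * base, rel=1e-3)

    @given(
        xx=st.floats(0.1, 100.0),
        yy=st.floats(0.0, 100.0),
        xy=st.floats(-50.0, 50.0),
    )
    def test_pure_relaxation_trace_decays_monotonically(self, xx, yy, xy):
        tau0 = SymmetricStressTensor(xx=xx, yy=yy, xy=xy)
        hist = integrate_stress(
            P_REF, KinematicsHistory.rest(), (0.0, 2 * P_REF.lambda_relax), tau0,
            t_eval=np.linspace(0.0, 2 * P_REF.lambda_relax, 50),
        )
        trace = hist.trace()
        assert np.all(np.diff(trace) <= 1e-12 * max(abs(trace[0]), 1.0))


class TestSteadyShearOracle:
    def test_zero_rate_gives_zero_stress(self):
        assert steady_simple_shear(P_REF, 0.0).as_vector().tolist() == [0.0] * 6

    def test_slow_shear_asymptotics(self):
        gamma_dot = 1e-3 / P_REF.lambda_relax
        tau = steady_simple_shear(P_REF, gamma_dot)
        assert tau.xy == pytest.approx(P_REF.eta_p * gamma_dot, rel=1e-4)
        n1 = 2.0 * P_REF.eta_p * P_REF.lambda_relax * gamma_dot**2
        assert tau.xx - tau.yy == pytest.approx(n1, rel=1e-3)

    @pytest.mark.parametrize("weissenberg", [0.01, 1.0, 10.0])
    def test_residual_of_steady_system(self, weissenberg):
        gamma_dot = weissenberg / P_REF.lambda_relax
        tau = steady_simple_shear(P_REF, gamma_dot)
        g = KinematicsHistory.simple_shear(gamma_dot).grad_u(0.0)
        rate = stress_rate(P_REF, tau, g)
        rel = (
            np.linalg.norm(rate.as_vector()) * P_REF.lambda_relax
            / np.linalg.norm(tau.as_vector())
        )
        assert rel < 1e-10

    def test_nonaffine_slip_not_supported(self):
        params = PTTParameters(1.0, 1.0, 0.01, zeta=0.1)
        with pytest.raises(NotImplementedError):
            steady_simple_shear(params, 1.0)


class TestContainers:
    def test_symmetric_tensor_round_trips(self):
        tau = SymmetricStressTensor(1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
        assert tau.trace == 6.0
        assert SymmetricStressTensor.from_matrix(tau.as_matrix()) == tau
        assert SymmetricStressTensor.from_vector(tau.as_vector()) == tau
        with pytest.raises(ValueError):
            SymmetricStressTensor.from_matrix(np.arange(9.0).reshape(3, 3))

    def test_history_csv_round_trip(self, tmp_path):
        hist = integrate_stress(
            P_REF,
            KinematicsHistory.simple_shear(0.1),
            (0.0, 1.0),
            t_eval=np.linspace(0.0, 1.0, 11),
        )
        path = tmp_path / "stress.csv"
        hist.to_csv(path)
        back = StressHistory.from_csv(path)
        assert np.allclose(back.times, hist.times)
        assert np.allclose(back.components, hist.components)
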