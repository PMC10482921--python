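"""Phan-Thien--Tanner (PTT) viscoelastic constitutive model.

The polymeric (fibrin-network) stress :math:`\\tau_p` evolves under a
Gordon--Schowalter derivative with an exponential destruction function

.. math::

    \\lambda\\,\\dot\\tau = \\eta_p(\\nabla u + \\nabla u^T)
        - f(\\tau)\\,\\tau
        + \\lambda\\left[\\tau\\,\\nabla u + (\\nabla u)^T\\tau
        - \\zeta(\\tau E + E\\tau)\\right],
    \\qquad
    f(\\tau) = \\exp\\!\\left(\\frac{\\varepsilon\\lambda}{\\eta_p}
        \\operatorname{tr}\\tau\\right),

where :math:`\\lambda` is the relaxation timescale, :math:`\\eta_p` the
polymeric viscosity (so :math:`G = \\eta_p/\\lambda` is the small-strain
elastic modulus), :math:`\\varepsilon` the extensibility parameter of the
destruction function and :math:`\\zeta` the non-affine slip parameter
(zero here: affine deformation of the network). The destruction function
collapses the stress once the dimensionless *fiber strain*
:math:`\\lambda\\operatorname{tr}(\\tau)/\\eta_p` becomes large, emulating
breakage of the subgrid fibrin/platelet network.

Conventions
-----------
* Axis 0 is streamwise/axial (x), axis 1 wall-normal (y), axis 2
  spanwise (z). This convention is used package-wide.
* The velocity-gradient tensor is stored as
  ``grad_u[i, j] = d u_j / d x_i``, so for simple shear
  ``u_x = gamma_dot * y`` the only nonzero entry is ``grad_u[1, 0]``.
  Use :meth:`KinematicsHistory.simple_shear` to avoid thinking about it.
* Only spatially homogeneous deformation histories are integrated (the
  advective term vanishes), which is what the compression and bond-layer
  reductions in this package require.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "PTTParameters",
    "SymmetricStressTensor",
    "KinematicsHistory",
    "StressHistory",
    "IntegrationError",
    "EXP_ARG_CAP",
    "breakage_factor",
    "fiber_strain",
    "stress_rate",
    "integrate_stress",
    "steady_simple_shear",
]

logger = logging.getLogger(__name__)

#: Cap on the argument of the exponential destruction function. The
#: destruction function is meant to collapse stress, not to overflow the
#: integrator; f <= exp(50) is far beyond any physically meaningful value.
EXP_ARG_CAP = 50.0

_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass(frozen=True)
class PTTParameters:
    """Constitutive parameter set (eta_p, lambda, epsilon, zeta).

    Parameters
    ----------
    eta_p : float
        Polymeric viscosity, Pa s. Must be positive.
    lambda_relax : float
        Relaxation timescale, s. Must be positive.
    epsilon : float, default 0.01
        Extensibility parameter of the destruction function,
        dimensionless. Larger epsilon breaks the network at lower
        stress. 0.01 is the customary bulk value.
    zeta : float, default 0.0
        Non-affine slip parameter of the Gordon--Schowalter derivative.
        Zero assumes affine deformation of the network.
    """

    eta_p: float
    lambda_relax: float
    epsilon: float = 0.01
    zeta: float = 0.0

    def __post_init__(self) -> None:
        if not (self.eta_p > 0 and math.isfinite(self.eta_p)):
            raise ValueError(f"eta_p must be positive and finite, got {self.eta_p}")
        if not (self.lambda_relax > 0 and math.isfinite(self.lambda_relax)):
            raise ValueError(
                f"lambda_relax must be positive and finite, got {self.lambda_relax}"
            )
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if not math.isfinite(self.zeta):
            raise ValueError("zeta must be finite")

    @property
    def modulus(self) -> float:
        """Small-strain elastic modulus G = eta_p / lambda, Pa."""
        return self.eta_p / self.lambda_relax

    def to_json_dict(self) -> dict:
        return {
            "eta_p_Pa_s": self.eta_p,
            "lambda_s": self.lambda_relax,
            "epsilon": self.epsilon,
            "zeta": self.zeta,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PTTParameters":
        return cls(
            eta_p=float(d["eta_p_Pa_s"]),
            lambda_relax=float(d["lambda_s"]),
            epsilon=float(d.get("epsilon", 0.01)),
            zeta=float(d.get("zeta", 0.0)),
        )


@dataclass(frozen=True)
class SymmetricStressTensor:
    """Polymeric stress carried as its six independent components, Pa.

    The reconstructed 3x3 matrix is exactly symmetric by construction.
    """

    xx: float = 0.0
    yy: float = 0.0
    zz: float = 0.0
    xy: float = 0.0
    xz: float = 0.0
    yz: float = 0.0

    @property
    def trace(self) -> float:
        return self.xx + self.yy + self.zz

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.xx, self.xy, self.xz],
                [self.xy, self.yy, self.yz],
                [self.xz, self.yz, self.zz],
            ]
        )

    def as_vector(self) -> np.ndarray:
        """Component vector in the fixed order (xx, yy, zz, xy, xz, yz)."""
        return np.array([self.xx, self.yy, self.zz, self.xy, self.xz, self.yz])

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "SymmetricStressTensor":
        v = np.asarray(v, dtype=float)
        if v.shape != (6,):
            raise ValueError(f"expected 6 components, got shape {v.shape}")
        return cls(*v)

    @classmethod
    def from_matrix(cls, m: np.ndarray, atol: float = 0.0) -> "SymmetricStressTensor":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("expected a 3x3 matrix")
        if not np.allclose(m, m.T, rtol=0.0, atol=atol):
            raise ValueError("matrix is not symmetric")
        return cls(m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2])

    @classmethod
    def zero(cls) -> "SymmetricStressTensor":
        return cls()


class KinematicsHistory:
    """Prescribed homogeneous velocity-gradient history t -> grad(u).

    Wraps a callable returning the 3x3 velocity-gradient tensor
    ``grad_u[i, j] = d u_j / d x_i`` (1/s) at time t. The symmetric part
    E = (grad_u + grad_u^T)/2 is derived on demand.
    """

    def __init__(self, grad_u_of_t: Callable[[float], np.ndarray]):
        self._fn = grad_u_of_t

    def grad_u(self, t: float) -> np.ndarray:
        g = np.asarray(self._fn(t), dtype=float)
        if g.shape != (3, 3):
            raise ValueError("velocity gradient must be 3x3")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"non-finite velocity gradient at t={t}")
        return g

    def sym(self, t: float) -> np.ndarray:
        g = self.grad_u(t)
        return 0.5 * (g + g.T)

    @classmethod
    def rest(cls) -> "KinematicsHistory":
        z = np.zeros((3, 3))
        return cls(lambda t: z)

    @classmethod
    def simple_shear(cls, shear_rate: float) -> "KinematicsHistory":
        """Steady simple shear u_x = gamma_dot * y."""
        g = np.zeros((3, 3))
        g[1, 0] = shear_rate
        return cls(lambda t: g)

    @classmethod
    def uniaxial(cls, axial_rate: Callable[[float], float] | float,
                 axis: int = 2) -> "KinematicsHistory":
        """Incompressible uniaxial deformation along ``axis``.

        ``axial_rate`` is the true strain rate along the axis (negative in
        compression); the lateral axes extend at -axial_rate/2.
        """
        rate = axial_rate if callable(axial_rate) else (lambda t, r=axial_rate: r)

        def fn(t: float) -> np.ndarray:
            e = rate(t)
            g = np.full(3, -0.5 * e)
            g[axis] = e
            return np.diag(g)

        return cls(fn)


class StressHistory:
    """Time series of symmetric stress states from an integration."""

    CSV_HEADER = ("time_s", "txx_Pa", "tyy_Pa", "tzz_Pa", "txy_Pa", "txz_Pa", "tyz_Pa")

    def __init__(self, times: np.ndarray, components: np.ndarray):
        times = np.asarray(times, dtype=float)
        components = np.asarray(components, dtype=float)
        if components.shape != (times.size, 6):
            raise ValueError("components must have shape (n_times, 6)")
        self.times = times
        self.components = components

    def __len__(self) -> int:
        return self.times.size

    def __getitem__(self, i: int) -> SymmetricStressTensor:
        return SymmetricStressTensor.from_vector(self.components[i])

    @property
    def final(self) -> SymmetricStressTensor:
        return self[-1]

    def trace(self) -> np.ndarray:
        return self.components[:, :3].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.times}
        for k, name in enumerate(self.CSV_HEADER[1:]):
            data[name] = self.components[:, k]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StressHistory":
        df = pd.read_csv(path)
        missing = set(cls.CSV_HEADER) - set(df.columns)
        if missing:
            raise ValueError(f"stress CSV missing columns: {sorted(missing)}")
        return cls(df["time_s"].to_numpy(), df[list(cls.CSV_HEADER[1:])].to_numpy())


class IntegrationError(RuntimeError):
    """Raised when the stress integration fails; carries the last state."""

    def __init__(self, message: str, t: float | None = None,
                 state: np.ndarray | None = None):
        super().__init__(message)
        self.t = t
        self.state = state


def _capped_exp_arg(arg: float) -> float:
    if arg > EXP_ARG_CAP:
        logger.warning(
            "breakage-function argument %.3g exceeds cap %.0f; clamping",
            arg, EXP_ARG_CAP,
        )
        return EXP_ARG_CAP
    return arg


def breakage_factor(params: PTTParameters,
                    tau: SymmetricStressTensor | float) -> float:
    """Exponential destruction function f = exp(eps*lambda/eta_p * tr(tau)).

    ``tau`` may be a stress tensor or the trace directly (Pa). Equals 1 at
    zero stress and grows monotonically with tr(tau) for epsilon > 0. The
    exponential argument is clamped at :data:`EXP_ARG_CAP` with a logged
    warning to keep runaway states finite.
    """
    tr = tau.trace if isinstance(tau, SymmetricStressTensor) else float(tau)
    arg = params.epsilon * params.lambda_relax / params.eta_p * tr
    return math.exp(_capped_exp_arg(arg))


def fiber_strain(params: PTTParameters,
                 tau: SymmetricStressTensor | float) -> float:
    """Dimensionless strain measure lambda * tr(tau) / eta_p."""
    tr = tau.trace if isinstance(tau, SymmetricStressTensor) else float(tau)
    return params.lambda_relax * tr / params.eta_p


def _rate_vector(params: PTTParameters, v: np.ndarray, g: np.ndarray) -> np.ndarray:
    """RHS of the evolution equation on the 6-component state vector."""
    tau = np.array(
        [
            [v[0], v[3], v[4]],
            [v[3], v[1], v[5]],
            [v[4], v[5], v[2]],
        ]
    )
    lam = params.lambda_relax
    tr = v[0] + v[1] + v[2]
    f = math.exp(_capped_exp_arg(params.epsilon * lam / params.eta_p * tr))
    gs = g + g.T
    rate = (params.eta_p * gs - f * tau) / lam + tau @ g + g.T @ tau
    if params.zeta != 0.0:
        e = 0.5 * gs
        rate -= params.zeta * (tau @ e + e @ tau)
    return np.array(
        [rate[0, 0], rate[1, 1], rate[2, 2], rate[0, 1], rate[0, 2], rate[1, 2]]
    )


def stress_rate(params: PTTParameters, tau: SymmetricStressTensor,
                grad_u: np.ndarray) -> SymmetricStressTensor:
    """Instantaneous stress rate (Pa/s) under a homogeneous deformation.

    Implements
    ``d tau/dt = (1/lambda)[eta_p (grad_u + grad_u^T) - f(tau) tau]
    + tau grad_u + grad_u^T tau - zeta (tau E + E tau)``
    with E the symmetric part of grad_u. The result is symmetric.
    """
    grad_u = np.asarray(grad_u, dtype=float)
    if grad_u.shape != (3, 3) or not np.all(np.isfinite(grad_u)):
        raise ValueError("grad_u must be a finite 3x3 tensor")
    if not np.all(np.isfinite(tau.as_vector())):
        raise ValueError("stress state must be finite")
    return SymmetricStressTensor.from_vector(
        _rate_vector(params, tau.as_vector(), grad_u)
    )


def integrate_stress(
    params: PTTParameters,
    kinematics: KinematicsHistory,
    t_span: tuple[float, float],
    tau0: SymmetricStressTensor | None = None,
    tol: float = 1e-8,
    t_eval: Iterable[float] | None = None,
    max_step: float = np.inf,
) -> StressHistory:
    """Integrate the stress evolution over ``t_span``.

    Uses an adaptive explicit Runge--Kutta scheme (RK45) on the symmetric
    6-component state vector with relative tolerance ``tol``; halving
    ``tol`` changes the final state by less than ``tol`` (self-convergence
    is the only accuracy contract, checked in the test suite against the
    algebraic steady-shear solution and the linearized relaxation closed
    form).
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError("t_span must be increasing")
    if not tol > 0:
        raise ValueError("tol must be positive")
    tau0 = tau0 if tau0 is not None else SymmetricStressTensor.zero()

    scale = max(abs(params.modulus), 1.0)  # stress scale for atol

    def rhs(t: float, v: np.ndarray) -> np.ndarray:
        return _rate_vector(params, v, kinematics.grad_u(t))

    sol = solve_ivp(
        rhs,
        (t0, t1),
        tau0.as_vector(),
        method="RK45",
        rtol=tol,
        atol=tol * scale * 1e-3,
        t_eval=None if t_eval is None else np.asarray(list(t_eval), dtype=float),
        max_step=max_step,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(
            f"stress integration failed: {sol.message}",
            t=float(sol.t[-1]) if sol.t.size else t0,
            state=sol.y[:, -1] if sol.y.size else None,
        )
    return StressHistory(sol.t, sol.y.T)


def steady_simple_shear(params: PTTParameters, shear_rate: float) -> SymmetricStressTensor:
    """Algebraic steady state under constant simple shear (oracle).

    Setting the stress rate to zero under simple shear (zeta = 0) gives
    ``tau_yy = tau_zz = 0``, ``f tau_xy = eta_p gamma_dot`` and
    ``f tau_xx = 2 lambda gamma_dot tau_xy``, hence a single scalar
    equation ``tau_xx f(tau_xx)^2 = 2 eta_p lambda gamma_dot^2`` solved by
    bracketed root finding on tr(tau) = tau_xx. Small-rate asymptotics:
    shear stress ~ eta_p gamma_dot, first normal-stress difference
    ~ 2 eta_p lambda gamma_dot^2.
    """
    if not math.isfinite(shear_rate):
        raise ValueError("shear_rate must be finite")
    if params.zeta != 0.0:
        raise NotImplementedError("steady-shear oracle is implemented for zeta = 0")
    g = float(shear_rate)
    if g == 0.0:
        return SymmetricStressTensor.zero()

    lam, eta = params.lambda_relax, params.eta_p
    rhs = 2.0 * eta * lam * g * g

    def resid(tr: float) -> float:
        f = breakage_factor(params, tr)
        return tr * f * f - rhs

    hi = rhs  # f >= 1 implies tr = rhs / f^2 <= rhs
    try:
        tr = brentq(resid, 0.0, hi * (1.0 + 1e-12), xtol=1e-280, rtol=8.9e-16)
    except ValueError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"root bracketing failed for steady shear at gamma_dot={g}"
        ) from exc
    f = breakage_factor(params, tr)
    tau_xy = eta * g / f
    tau = SymmetricStressTensor(xx=tr, xy=tau_xy)
    # residual check of the full steady-state system, relative norm
    rate = _rate_vector(params, tau.as_vector(), KinematicsHistory.simple_shear(g).grad_u(0.0))
    rel = np.linalg.norm(rate) * lam / max(np.linalg.norm(tau.as_vector()), 1e-300)
    if rel > 1e-8:  # pragma: no cover - defensive
        raise RuntimeError(f"steady-shear residual too large: {rel:.3e}")
    return tau
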