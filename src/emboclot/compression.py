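"""Stress-relaxation compression test: simulation and parameter fitting.

A cylindrical clot is compressed between platens at a constant platen
speed to a target strain (default 10% over 1 s) and held (default 30 s)
while the axial stress relaxes. The sample is treated as an
incompressible PTT material under *homogeneous* uniaxial deformation:

* axial true strain rate  ``e(t) = h'(t)/h(t)`` (negative in
  compression), lateral rates ``-e/2``;
* traction-free lateral closure: the measured axial stress is the
  deviatoric normal-stress difference of the polymeric stress.

The compressive stress is reported positive, matching how platen-force
data are plotted: ``sigma(t) = tau_lat - tau_ax`` with the compression
axis taken as axis 2 (z). For a homogeneous sample this equals the
platen force divided by the current contact area (A(t) = V/h(t) by
incompressibility).

Fitting (eta_p, lambda) to a measured or synthetic curve is exposed in
the Model/Results idiom::

    model = StressRelaxationModel(curve, protocol)
    res = model.fit()
    res.params, res.r_squared, print(res.summary())
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constitutive import (
    KinematicsHistory,
    PTTParameters,
    SymmetricStressTensor,
    integrate_stress,
)

__all__ = [
    "CompressionProtocol",
    "StressRelaxationCurve",
    "simulate_compression",
    "synth_relaxation_curve",
    "r_squared",
    "StressRelaxationModel",
    "StressRelaxationResults",
]

_MIN_FIT_POINTS = 10


@dataclass(frozen=True)
class CompressionProtocol:
    """Ramp-and-hold compression protocol.

    The platen moves at the constant speed
    ``v = target_strain * initial_height / ramp_duration`` during the
    ramp (for a 1-s ramp to 10% this coincides with "10% per second"),
    then holds. The *true* strain rate e(t) = -v/h(t) is what enters the
    velocity gradient.
    """

    initial_height: float = 0.010  # m
    ramp_duration: float = 1.0  # s
    target_strain: float = 0.10  # engineering strain, dimensionless
    hold_duration: float = 30.0  # s

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_strain < 1.0:
            raise ValueError("target_strain must be in [0, 1)")
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be positive")
        if self.hold_duration < 0:
            raise ValueError("hold_duration must be >= 0")
        if self.initial_height <= 0:
            raise ValueError("initial_height must be positive")

    @property
    def platen_speed(self) -> float:
        return self.target_strain * self.initial_height / self.ramp_duration

    @property
    def duration(self) -> float:
        return self.ramp_duration + self.hold_duration

    def height(self, t: float) -> float:
        t_ramp = min(max(t, 0.0), self.ramp_duration)
        return self.initial_height - self.platen_speed * t_ramp

    def axial_strain_rate(self, t: float) -> float:
        """True axial strain rate h'/h, negative during the ramp."""
        if 0.0 <= t < self.ramp_duration:
            return -self.platen_speed / self.height(t)
        return 0.0

    def kinematics(self) -> KinematicsHistory:
        return KinematicsHistory.uniaxial(self.axial_strain_rate, axis=2)


@dataclass
class StressRelaxationCurve:
    """Axial stress time series from a compression protocol.

    ``axial_stress`` is the compressive stress, Pa, positive in
    compression, defined as platen force divided by the *current*
    cross-sectional area. Raw force records (dialect B) are converted via
    the sample dimensions and incompressibility.
    """

    time: np.ndarray
    axial_stress: np.ndarray
    force: np.ndarray | None = None
    sample_height: float | None = None
    sample_diameter: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.axial_stress = np.asarray(self.axial_stress, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.axial_stress.shape:
            raise ValueError("time and axial_stress must be 1-D arrays of equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.axial_stress)):
            raise ValueError("stress values must be finite")

    def __len__(self) -> int:
        return self.time.size

    @classmethod
    def from_force(
        cls,
        time: Sequence[float],
        force: Sequence[float],
        displacement: Sequence[float],
        sample_height: float,
        sample_diameter: float,
    ) -> "StressRelaxationCurve":
        """Instrument-style record: force (N) and platen displacement (m).

        Converts to current-area stress using incompressibility,
        A(t) = V / h(t) with h(t) = sample_height - displacement(t).
        """
        time = np.asarray(time, dtype=float)
        force = np.asarray(force, dtype=float)
        disp = np.asarray(displacement, dtype=float)
        volume = math.pi * (sample_diameter / 2.0) ** 2 * sample_height
        h = sample_height - disp
        if np.any(h <= 0):
            raise ValueError("displacement exceeds sample height")
        stress = force / (volume / h)
        return cls(
            time=time,
            axial_stress=stress,
            force=force,
            sample_height=sample_height,
            sample_diameter=sample_diameter,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "stress_Pa": self.axial_stress}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(
        cls,
        path,
        sample_height: float | None = None,
        sample_diameter: float | None = None,
    ) -> "StressRelaxationCurve":
        """Read dialect A (``time_s,stress_Pa``) or dialect B
        (``time_s,force_N,displacement_m`` plus sample dimensions)."""
        df = pd.read_csv(path)
        cols = set(df.columns)
        if {"time_s", "stress_Pa"} <= cols:
            return cls(df["time_s"].to_numpy(), df["stress_Pa"].to_numpy())
        if {"time_s", "force_N", "displacement_m"} <= cols:
            if sample_height is None or sample_diameter is None:
                raise ValueError(
                    "force-dialect CSV requires sample_height and sample_diameter"
                )
            return cls.from_force(
                df["time_s"].to_numpy(),
                df["force_N"].to_numpy(),
                df["displacement_m"].to_numpy(),
                sample_height,
                sample_diameter,
            )
        raise ValueError(
            "unrecognized stress-relaxation CSV dialect; expected columns "
            "(time_s, stress_Pa) or (time_s, force_N, displacement_m), got "
            f"{sorted(cols)}"
        )


def simulate_compression(
    params: PTTParameters,
    protocol: CompressionProtocol,
    sample_times: Sequence[float],
    tol: float = 1e-8,
    stress_basis: str = "current_area",
) -> StressRelaxationCurve:
    """Simulate the ramp-and-hold test under homogeneous deformation.

    Returns the compressive axial stress at ``sample_times``. With
    ``stress_basis="initial_area"`` the force-per-initial-area
    (engineering) stress is returned instead; the default divides by the
    current area, which for this homogeneous closure is the normal-stress
    difference itself.
    """
    t = np.asarray(sample_times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("sample_times must be a non-empty 1-D sequence")
    if np.any(t < 0) or np.any(t > protocol.duration + 1e-12):
        raise ValueError("sample_times must lie within [0, ramp + hold]")
    if not np.all(np.diff(t) > 0):
        raise ValueError("sample_times must be strictly increasing")
    if stress_basis not in ("current_area", "initial_area"):
        raise ValueError("stress_basis must be 'current_area' or 'initial_area'")

    if protocol.target_strain == 0.0:
        return StressRelaxationCurve(t, np.zeros_like(t))

    kin = protocol.kinematics()
    t_ramp = protocol.ramp_duration

    # integrate the two phases separately: the strain rate is
    # discontinuous at the end of the ramp
    comps = np.empty((t.size, 6))
    mask_ramp = t <= t_ramp
    eval_ramp, eval_hold = t[mask_ramp], t[~mask_ramp]

    grid_ramp = np.union1d(eval_ramp, [0.0, t_ramp])
    hist_ramp = integrate_stress(
        params, kin, (0.0, t_ramp), SymmetricStressTensor.zero(),
        tol=tol, t_eval=grid_ramp,
    )
    comps[mask_ramp] = hist_ramp.components[
        np.searchsorted(hist_ramp.times, eval_ramp)
    ]
    tau_state = hist_ramp.final

    if eval_hold.size:
        grid_hold = np.union1d(eval_hold, [t_ramp])
        hist_hold = integrate_stress(
            params, kin, (t_ramp, grid_hold[-1]), tau_state, tol=tol, t_eval=grid_hold
        )
        comps[~mask_ramp] = hist_hold.components[
            np.searchsorted(hist_hold.times, eval_hold)
        ]

    # compressive stress, positive: lateral minus axial normal stress
    sigma = comps[:, 0] - comps[:, 2]
    if stress_basis == "initial_area":
        h = np.array([protocol.height(tt) for tt in t])
        sigma = sigma * protocol.initial_height / h  # A(t)/A0 = h0/h
    return StressRelaxationCurve(t, sigma)


def synth_relaxation_curve(
    params: PTTParameters,
    protocol: CompressionProtocol,
    noise_sd_fraction: float = 0.0,
    seed: int = 0,
    n_samples: int = 311,
    tol: float = 1e-8,
) -> StressRelaxationCurve:
    """Synthetic stress-relaxation curve: simulation plus multiplicative
    Gaussian noise (relative SD ``noise_sd_fraction``), reproducible per
    seed."""
    if noise_sd_fraction < 0:
        raise ValueError("noise_sd_fraction must be >= 0")
    times = np.linspace(0.0, protocol.duration, n_samples)[1:]  # skip t=0 (zero stress)
    clean = simulate_compression(params, protocol, times, tol=tol)
    stress = clean.axial_stress
    if noise_sd_fraction > 0:
        rng = np.random.default_rng(seed)
        stress = stress * (1.0 + noise_sd_fraction * rng.standard_normal(stress.size))
    return StressRelaxationCurve(times, stress)


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-D, n >= 2")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0.0:
        raise ValueError("observed series has zero variance; R^2 undefined")
    ss_res = np.sum((obs - pred) ** 2)
    return 1.0 - ss_res / ss_tot


class StressRelaxationModel:
    """Fit PTT parameters (eta_p, lambda) to a stress-relaxation curve.

    Least squares on stress between :func:`simulate_compression` and the
    observed curve, in log-parameter space, with a deterministic
    log-spaced multi-start grid (eta_p in [1e2, 1e7] Pa s, lambda in
    [0.1, 100] s). The extensibility parameter is held fixed
    (default 0.01) as it is not identifiable from small-strain data.
    """

    ETA_BOUNDS = (1e2, 1e7)
    LAMBDA_BOUNDS = (0.1, 100.0)

    def __init__(
        self,
        curve: StressRelaxationCurve,
        protocol: CompressionProtocol,
        epsilon_fixed: float = 0.01,
        zeta: float = 0.0,
    ):
        if len(curve) < _MIN_FIT_POINTS:
            raise ValueError(f"need at least {_MIN_FIT_POINTS} samples to fit")
        self.curve = curve
        self.protocol = protocol
        self.epsilon_fixed = epsilon_fixed
        self.zeta = zeta

    def _params(self, log_eta: float, log_lam: float) -> PTTParameters:
        return PTTParameters(
            eta_p=math.exp(log_eta),
            lambda_relax=math.exp(log_lam),
            epsilon=self.epsilon_fixed,
            zeta=self.zeta,
        )

    def _residuals(self, x: np.ndarray, tol: float) -> np.ndarray:
        sim = simulate_compression(
            self._params(x[0], x[1]), self.protocol, self.curve.time, tol=tol
        )
        return sim.axial_stress - self.curve.axial_stress

    def fit(
        self,
        n_starts: tuple[int, int] = (6, 7),
        refine_top: int = 3,
        sim_tol: float = 1e-6,
    ) -> "StressRelaxationResults":
        """Multi-start nonlinear least squares.

        The coarse grid objective is evaluated at ``n_starts`` log-spaced
        (eta_p, lambda) nodes; the ``refine_top`` best starts are refined
        with trust-region least squares and the best refined optimum is
        returned. Deterministic for a fixed grid. Non-convergence of all
        starts raises rather than returning silently.
        """
        etas = np.log(np.geomspace(*self.ETA_BOUNDS, n_starts[0]))
        lams = np.log(np.geomspace(*self.LAMBDA_BOUNDS, n_starts[1]))
        grid = [(le, ll) for le in etas for ll in lams]
        costs = []
        for le, ll in grid:
            r = self._residuals(np.array([le, ll]), tol=max(sim_tol, 1e-6))
            costs.append(float(np.sum(r * r)))
        order = np.argsort(costs, kind="stable")[:refine_top]

        bounds = (
            [math.log(self.ETA_BOUNDS[0]), math.log(self.LAMBDA_BOUNDS[0])],
            [math.log(self.ETA_BOUNDS[1]), math.log(self.LAMBDA_BOUNDS[1])],
        )
        best = None
        any_converged = False
        for idx in order:
            sol = least_squares(
                self._residuals,
                np.array(grid[idx]),
                bounds=bounds,
                args=(sim_tol,),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            any_converged = any_converged or sol.success
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not any_converged:
            raise RuntimeError(
                "stress-relaxation fit failed to converge from any start"
            )
        params = self._params(*best.x)
        pred = simulate_compression(params, self.protocol, self.curve.time, tol=1e-8)
        r2 = r_squared(self.curve.axial_stress, pred.axial_stress)
        return StressRelaxationResults(
            model=self,
            params=params,
            r_squared=r2,
            rss=float(2.0 * best.cost),
            converged=bool(best.success),
            n_points=len(self.curve),
            fitted_curve=pred,
        )


@dataclass
class StressRelaxationResults:
    """Fit result: parameter estimates, goodness of fit, diagnostics."""

    model: StressRelaxationModel
    params: PTTParameters
    r_squared: float
    rss: float
    converged: bool
    n_points: int
    fitted_curve: StressRelaxationCurve

    @property
    def modulus(self) -> float:
        """Implied small-strain elastic modulus eta_p / lambda, Pa."""
        return self.params.modulus

    def to_json_dict(self) -> dict:
        return {
            "eta_p_Pa_s": self.params.eta_p,
            "lambda_s": self.params.lambda_relax,
            "modulus_Pa": self.modulus,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "converged": self.converged,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            "Stress-relaxation fit (PTT, homogeneous uniaxial closure)",
            "=" * 58,
            f"n points            {self.n_points:>12d}",
            f"converged           {str(self.converged):>12s}",
            f"eta_p  [Pa s]       {self.params.eta_p:>12.4g}",
            f"lambda [s]          {self.params.lambda_relax:>12.4g}",
            f"modulus G [Pa]      {self.modulus:>12.4g}",
            f"epsilon (fixed)     {self.params.epsilon:>12.4g}",
            f"R^2                 {self.r_squared:>12.4f}",
            f"RSS [Pa^2]          {self.rss:>12.4g}",
        ]
        return "\n".join(lines)

    def resimulate(self) -> StressRelaxationCurve:
        return simulate_compression(self.params, self.model.protocol, self.model.curve.time)

    def plot(self, ax=None):
        """Observed vs fitted stress-relaxation curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.curve.time, self.model.curve.axial_stress, ".",
                ms=3, label="observed")
        ax.plot(self.fitted_curve.time, self.fitted_curve.axial_stress, "-",
                label="fitted")
        ax.set_xlabel("time [s]")
        ax.set_ylabel("compressive stress [Pa]")
        ax.legend()
        return ax
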