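"""Hydrodynamic loading of the clot in turbulent pipe flow.

Characterizes the flow conditions (mean velocity, Reynolds number,
transit timescale T = D/U), near-wall quantities in wall units, the
classical log-law reference profile, and the drag force on the clot.

The drag force at the five simulated flow rates (1.9, 2.8, 4.2, 6.3 and
10 LPM, from full-resolution large-eddy/VOF simulations of the same
configuration) is shipped as a packaged fixture
(``data/table1_drag.csv``). The drag coefficient is

.. math:: C_D = \\frac{2 F_D}{\\rho A U^2}

with the fixed projected-area constant A = 0.181 cm^2. A drag-vs-flow
model is fitted to these records in the Model/Results idiom::

    res = DragLawModel(load_drag_table()).fit()      # F = c Q^p
    res.predict(4.2)                                 # N

The default model is a single power law fitted by least squares in
log-log space (drag is near-quadratic in velocity); a piecewise log-log
interpolant passing exactly through the knots is available with
``fit(kind="piecewise")``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d

__all__ = [
    "LPM_TO_M3_PER_S",
    "PROJECTED_AREA_M2",
    "DEFAULT_DIAMETER_M",
    "FlowCondition",
    "WallUnits",
    "DragRecord",
    "flow_condition",
    "drag_coefficient",
    "drag_force_from_coefficient",
    "load_drag_table",
    "drag_records",
    "DragLawModel",
    "DragLawResults",
    "loglaw_velocity",
    "viscous_sublayer_velocity",
    "wall_units",
    "linear_stress_profile",
]

logger = logging.getLogger(__name__)

LPM_TO_M3_PER_S = 1.0 / 60000.0  # exact
#: Projected (frontal) area constant used for drag-coefficient
#: normalization of the reference clot, m^2 (0.181 cm^2).
PROJECTED_AREA_M2 = 0.181e-4
DEFAULT_DIAMETER_M = 0.0127
DEFAULT_NU_M2_S = 1e-6  # phosphate-buffered saline at 20 C
DEFAULT_RHO_KG_M3 = 1000.0


@dataclass(frozen=True)
class FlowCondition:
    """Bulk flow condition in a circular tube.

    Derived fields satisfy U = Q/(pi D^2/4), Re = U D / nu, T = D/U.
    """

    Q_lpm: float
    diameter: float = DEFAULT_DIAMETER_M
    nu: float = DEFAULT_NU_M2_S
    rho: float = DEFAULT_RHO_KG_M3

    def __post_init__(self) -> None:
        for name in ("Q_lpm", "diameter", "nu", "rho"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @property
    def Q(self) -> float:
        """Volumetric flow rate, m^3/s."""
        return self.Q_lpm * LPM_TO_M3_PER_S

    @property
    def area(self) -> float:
        return math.pi * self.diameter**2 / 4.0

    @property
    def mean_velocity(self) -> float:
        return self.Q / self.area

    @property
    def reynolds(self) -> float:
        return self.mean_velocity * self.diameter / self.nu

    @property
    def timescale(self) -> float:
        """Characteristic (transit) timescale T = D/U, s."""
        return self.diameter / self.mean_velocity

    def to_json_dict(self) -> dict:
        return {
            "Q_LPM": self.Q_lpm,
            "Q_m3_s": self.Q,
            "D_m": self.diameter,
            "nu_m2_s": self.nu,
            "rho_kg_m3": self.rho,
            "U_m_s": self.mean_velocity,
            "Re": self.reynolds,
            "T_s": self.timescale,
        }


def flow_condition(Q_lpm: float, diameter: float = DEFAULT_DIAMETER_M,
                   nu: float = DEFAULT_NU_M2_S,
                   rho: float = DEFAULT_RHO_KG_M3) -> FlowCondition:
    """Build a :class:`FlowCondition` from a flow rate in LPM."""
    return FlowCondition(Q_lpm=Q_lpm, diameter=diameter, nu=nu, rho=rho)


def drag_coefficient(F_D: float, rho: float, A: float, U: float) -> float:
    """C_D = 2 F_D / (rho A U^2)."""
    if A <= 0 or U <= 0:
        raise ValueError("A and U must be positive")
    return 2.0 * F_D / (rho * A * U * U)


def drag_force_from_coefficient(C_D: float, rho: float, A: float, U: float) -> float:
    """Inverse of :func:`drag_coefficient`; the pair round-trips exactly."""
    if A <= 0 or U <= 0:
        raise ValueError("A and U must be positive")
    return 0.5 * C_D * rho * A * U * U


@dataclass(frozen=True)
class DragRecord:
    """Drag force on the clot at one flow condition."""

    flow: FlowCondition
    F_D: float  # N
    C_D: float  # dimensionless
    A: float = PROJECTED_AREA_M2  # m^2


@dataclass(frozen=True)
class WallUnits:
    """Near-wall quantities and grid spacings in wall units."""

    tau_w: float  # Pa
    u_tau: float  # m/s
    wall_shear_rate: float  # 1/s
    dx_plus: float
    dy_plus: float
    dz_plus: float


def wall_units(tau_w: float, rho: float = DEFAULT_RHO_KG_M3,
               nu: float = DEFAULT_NU_M2_S,
               spacings: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> WallUnits:
    """Friction velocity u_tau = sqrt(tau_w/rho), wall shear rate
    tau_w/(rho nu), and grid spacings (dx, dy, dz) in wall units."""
    if tau_w < 0:
        raise ValueError("tau_w must be >= 0")
    u_tau = math.sqrt(tau_w / rho)
    dx, dy, dz = spacings
    return WallUnits(
        tau_w=tau_w,
        u_tau=u_tau,
        wall_shear_rate=tau_w / (rho * nu),
        dx_plus=dx * u_tau / nu,
        dy_plus=dy * u_tau / nu,
        dz_plus=dz * u_tau / nu,
    )


def loglaw_velocity(y_plus: float | np.ndarray) -> float | np.ndarray:
    """Classical log-law of the wall, u+ = ln(y+)/0.41 + 5.0."""
    y_plus = np.asarray(y_plus, dtype=float)
    if np.any(y_plus <= 0):
        raise ValueError("y_plus must be positive")
    out = np.log(y_plus) / 0.41 + 5.0
    return float(out) if out.ndim == 0 else out


def viscous_sublayer_velocity(y_plus: float | np.ndarray) -> float | np.ndarray:
    """Viscous-sublayer line u+ = y+."""
    y_plus = np.asarray(y_plus, dtype=float)
    return float(y_plus) if y_plus.ndim == 0 else y_plus.copy()


def linear_stress_profile(y_over_R: float | np.ndarray) -> float | np.ndarray:
    """Reference line 1 - y/R: Reynolds shear stress decreasing linearly
    to zero at the tube center (diagnostic/plot aid)."""
    y = np.asarray(y_over_R, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y/R must lie in [0, 1]")
    out = 1.0 - y
    return float(out) if out.ndim == 0 else out


def load_drag_table() -> pd.DataFrame:
    """Packaged drag table (columns Q_LPM, F_D_N, C_D), quoted to the
    precision of the reference simulations."""
    with resources.files("emboclot.data").joinpath("table1_drag.csv").open() as fh:
        return pd.read_csv(fh)


def drag_records(table: pd.DataFrame | None = None,
                 diameter: float = DEFAULT_DIAMETER_M,
                 nu: float = DEFAULT_NU_M2_S,
                 rho: float = DEFAULT_RHO_KG_M3) -> list[DragRecord]:
    """Wrap a drag table into :class:`DragRecord` objects."""
    if table is None:
        table = load_drag_table()
    records = []
    for _, row in table.iterrows():
        flow = flow_condition(float(row["Q_LPM"]), diameter, nu, rho)
        records.append(
            DragRecord(flow=flow, F_D=float(row["F_D_N"]), C_D=float(row["C_D"]))
        )
    return records


class DragLawModel:
    """Drag force vs flow rate, fitted to tabulated (Q, F_D) records."""

    def __init__(self, records: pd.DataFrame | Sequence[DragRecord]):
        if isinstance(records, pd.DataFrame):
            Q = records["Q_LPM"].to_numpy(dtype=float)
            F = records["F_D_N"].to_numpy(dtype=float)
        else:
            Q = np.array([r.flow.Q_lpm for r in records], dtype=float)
            F = np.array([r.F_D for r in records], dtype=float)
        if Q.size < 2 or np.unique(Q).size < 2:
            raise ValueError("need at least 2 records with distinct Q")
        if np.any(Q <= 0) or np.any(F <= 0):
            raise ValueError("Q and F_D must be positive (log-log fit domain)")
        order = np.argsort(Q)
        self.Q = Q[order]
        self.F = F[order]

    def fit(self, kind: str = "power") -> "DragLawResults":
        """Fit the drag law.

        ``kind="power"``: single power law F = c Q^p, least squares in
        log-log space over all records (default).
        ``kind="piecewise"``: linear interpolation in log-log space,
        exact at the knots.
        """
        logQ, logF = np.log(self.Q), np.log(self.F)
        if kind == "power":
            p, logc = np.polyfit(logQ, logF, 1)
            c = math.exp(logc)
            predict = lambda q: c * np.asarray(q, dtype=float) ** p
        elif kind == "piecewise":
            itp = interp1d(logQ, logF, kind="linear", fill_value="extrapolate")
            c = p = math.nan
            predict = lambda q: np.exp(itp(np.log(np.asarray(q, dtype=float))))
        else:
            raise ValueError("kind must be 'power' or 'piecewise'")
        residuals = predict(self.Q) - self.F
        return DragLawResults(
            model=self, kind=kind, coefficient=c, exponent=p,
            _predict=predict, residuals=residuals,
        )


@dataclass
class DragLawResults:
    """Fitted drag law; ``predict`` maps Q (LPM) to drag force (N)."""

    model: DragLawModel
    kind: str
    coefficient: float  # c in F = c Q^p (N per LPM^p); nan for piecewise
    exponent: float  # p; nan for piecewise
    _predict: callable
    residuals: np.ndarray

    def predict(self, Q_lpm: float | np.ndarray) -> float | np.ndarray:
        """Drag force in N at flow rate(s) in LPM. Evaluation outside the
        fitted Q range logs an extrapolation warning."""
        q = np.asarray(Q_lpm, dtype=float)
        if np.any(q <= 0):
            raise ValueError("Q must be positive")
        if np.any(q < self.model.Q[0]) or np.any(q > self.model.Q[-1]):
            logger.warning(
                "drag model evaluated outside fitted range [%g, %g] LPM",
                self.model.Q[0], self.model.Q[-1],
            )
        out = self._predict(q)
        return float(out) if np.ndim(out) == 0 else np.asarray(out)

    def __call__(self, Q_lpm):
        return self.predict(Q_lpm)

    def summary(self) -> str:
        lines = [
            "Drag law fit",
            "=" * 40,
            f"kind            {self.kind:>12s}",
        ]
        if self.kind == "power":
            lines += [
                f"c [N/LPM^p]     {self.coefficient:>12.4e}",
                f"exponent p      {self.exponent:>12.4f}",
            ]
        lines.append("residuals at knots [N]:")
        for q, r in zip(self.model.Q, self.residuals):
            lines.append(f"  Q = {q:5.2f} LPM   {r:+.3e}")
        return "\n".join(lines)

    def plot(self, ax=None, q_grid: np.ndarray | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if q_grid is None:
            q_grid = np.geomspace(self.model.Q[0], self.model.Q[-1], 100)
        ax.loglog(self.model.Q, self.model.F * 1e3, "o", label="records")
        ax.loglog(q_grid, self.predict(q_grid) * 1e3, "-", label=f"{self.kind} fit")
        ax.set_xlabel("Q [LPM]")
        ax.set_ylabel("drag force [mN]")
        ax.legend()
        return ax
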