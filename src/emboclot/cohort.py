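"""Synthetic embolization cohorts and their mapping onto drag forces.

The in-vitro experiments recorded, for each clot, the flow rate at
which it embolized; only summary statistics were published (n = 32,
mean 5.1 LPM, SD 1.1 LPM, range 2.3-7.5 LPM, clot length
14.2 +/- 1.7 mm). The generator here draws embolization flow rates from
a truncated normal on the published range whose *truncated* mean and SD
are moment-matched to the published values (the parent parameters are
found by root solving), and clot lengths from a normal floored at 1 mm.

Sampled cohorts are mapped through a fitted drag law (Q -> F_D) and,
optionally, through a user-supplied threshold curve (Q -> eps_wt) to
produce per-sample embolization drag forces and threshold wall
extensibility parameters with summary statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CohortSpec",
    "calibrate_truncnorm",
    "sample_cohort",
    "map_cohort",
    "cohort_summary",
]

logger = logging.getLogger(__name__)

_MIN_LENGTH_MM = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Cohort generator settings; defaults reproduce the published
    experimental summary statistics."""

    n: int = 32
    mean_Q: float = 5.1  # LPM
    sd_Q: float = 1.1  # LPM
    Q_range: tuple[float, float] = (2.3, 7.5)  # LPM
    mean_length: float = 14.2  # mm
    sd_length: float = 1.7  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.Q_range
        if not lo < self.mean_Q < hi:
            raise ValueError("Q_range must bracket mean_Q")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_Q < 0 or self.sd_length < 0:
            raise ValueError("standard deviations must be >= 0")


def _truncated_moments(mu: float, sigma: float,
                       bounds: tuple[float, float]) -> tuple[float, float]:
    lo, hi = bounds
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def calibrate_truncnorm(
    target_mean: float,
    target_sd: float,
    bounds: tuple[float, float],
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Parent-normal (mu, sigma) whose truncation to ``bounds`` has the
    requested mean and SD.

    Moment matching by numerical root solving; the achieved truncated
    moments are re-evaluated and must agree with the targets within
    1e-6. Unbounded intervals return (target_mean, target_sd) directly.
    Infeasible targets (SD too large for the interval: the truncated SD
    cannot exceed (hi-lo)/sqrt(12), the uniform limit) are reported.
    """
    lo, hi = bounds
    if math.isinf(lo) and math.isinf(hi):
        return target_mean, target_sd
    if not (lo < target_mean < hi):
        raise ValueError("target_mean must lie strictly inside bounds")
    if target_sd <= 0:
        raise ValueError("target_sd must be positive")
    sd_max = (hi - lo) / math.sqrt(12.0)
    if target_sd >= sd_max:
        raise ValueError(
            f"target_sd={target_sd:g} infeasible on [{lo:g}, {hi:g}]: the "
            f"truncated SD is bounded by the uniform limit {sd_max:g}"
        )

    def resid(x: np.ndarray) -> list[float]:
        m, s = _truncated_moments(x[0], math.exp(x[1]), bounds)
        return [m - target_mean, s - target_sd]

    sol = optimize.root(resid, [target_mean, math.log(target_sd)], tol=tol)
    mu, sigma = float(sol.x[0]), float(math.exp(sol.x[1]))
    m, s = _truncated_moments(mu, sigma, bounds)
    if abs(m - target_mean) > 1e-6 or abs(s - target_sd) > 1e-6:
        raise RuntimeError(
            f"truncated-normal calibration did not converge: achieved "
            f"mean {m:.8f}, SD {s:.8f}"
        )
    return mu, sigma


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a reproducible cohort: columns sample_id, Q_LPM,
    clot_length_mm.

    Flow rates come from the moment-calibrated truncated normal; clot
    lengths from an (untruncated) normal floored at 1 mm.
    """
    mu, sigma = calibrate_truncnorm(spec.mean_Q, spec.sd_Q, spec.Q_range)
    lo, hi = spec.Q_range
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    rng = np.random.default_rng(spec.seed)
    Q = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=spec.n, random_state=rng)
    length = spec.mean_length + spec.sd_length * rng.standard_normal(spec.n)
    length = np.maximum(length, _MIN_LENGTH_MM)
    return pd.DataFrame(
        {
            "sample_id": np.arange(spec.n),
            "Q_LPM": Q,
            "clot_length_mm": length,
        }
    )


def map_cohort(
    samples: pd.DataFrame,
    drag_law: Callable[[np.ndarray], np.ndarray],
    threshold_curve: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Map embolization flow rates onto drag forces (and optionally
    threshold wall extensibility parameters).

    ``drag_law`` maps Q in LPM to drag force in N (a fitted
    :class:`~emboclot.pipeflow.DragLawResults` works directly; it logs a
    warning if any Q falls outside its fitted domain).
    ``threshold_curve``, if given, maps Q in LPM to eps_wt.

    Returns the augmented frame and a summary dict with mean/sd/min/max
    of the mapped quantities (SDs use the n-1 convention; a cohort of
    size 1 reports SD 0).
    """
    out = samples.copy()
    Q = out["Q_LPM"].to_numpy(dtype=float)
    F = np.asarray(drag_law(Q), dtype=float)
    out["F_D_N"] = F
    if threshold_curve is not None:
        out["eps_wt"] = np.asarray(threshold_curve(Q), dtype=float)
    return out, cohort_summary(out)


def cohort_summary(mapped: pd.DataFrame) -> dict:
    """Summary statistics of a mapped cohort."""

    def block(x: np.ndarray) -> dict:
        return {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "min": float(np.min(x)),
            "max": float(np.max(x)),
        }

    summary = {
        "n": int(len(mapped)),
        "Q_LPM": block(mapped["Q_LPM"].to_numpy(dtype=float)),
    }
    if "F_D_N" in mapped:
        summary["F_D_N"] = block(mapped["F_D_N"].to_numpy(dtype=float))
    if "eps_wt" in mapped:
        summary["eps_wt"] = block(mapped["eps_wt"].to_numpy(dtype=float))
    if "clot_length_mm" in mapped:
        summary["clot_length_mm"] = block(mapped["clot_length_mm"].to_numpy(dtype=float))
    return summary
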