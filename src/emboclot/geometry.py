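"""Clot-in-tube geometry.

The clot occupying the bottom of a tube of diameter ``D`` is modeled as
the intersection of the tube interior with a cylinder whose axis is
oriented spanwise (perpendicular to the tube axis, horizontal). The clot
is described by its height ``h`` above the bottom of the tube wall and
its maximum streamwise chord ``L``, attained at the tube bottom (for the
reference clot the spanwise-cylinder center lies below the tube, so the
widest section is at the wall; this is the only reading consistent with
the reference volume).

Coordinates: x streamwise, y wall-normal measured from the lowest point
of the tube interior, z spanwise; the clot is centered at x = 0. At
height ``u`` above the tube bottom a cross-section of the clot is the
rectangle ``|x| <= a(u)``, ``|z| <= b(u)`` with

* ``a(u) = sqrt(Rc^2 - (u + Rc - h)^2)`` (spanwise-cylinder constraint),
* ``b(u) = sqrt(u (D - u))`` (tube-wall constraint),

because the two constraints act on disjoint coordinates. All quantities
are SI internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad

__all__ = [
    "TubeGeometry",
    "ClotGeometry",
    "spanwise_cylinder_radius",
    "bottom_chord",
    "frontal_area",
    "clot_volume",
    "contact_area",
    "monte_carlo_volume",
    "monte_carlo_contact_area",
]


@dataclass(frozen=True)
class TubeGeometry:
    """Circular tube; ``diameter`` in meters (default 12.7 mm)."""

    diameter: float = 0.0127

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("tube diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def spanwise_cylinder_radius(h: float, L: float) -> float:
    """Radius of the spanwise cylinder from the bottom-chord relation.

    Solves ``L = 2 sqrt(h (2 Rc - h))`` for Rc, i.e.
    ``Rc = (L^2/4 + h^2) / (2 h)``. Round-trips with
    :func:`bottom_chord` to machine precision.
    """
    if h <= 0 or L <= 0:
        raise ValueError("h and L must be positive")
    return (L * L / 4.0 + h * h) / (2.0 * h)


def bottom_chord(h: float, R_c: float) -> float:
    """Inverse of :func:`spanwise_cylinder_radius`: L = 2 sqrt(h(2Rc-h))."""
    if h <= 0 or R_c < h / 2.0:
        raise ValueError("require h > 0 and R_c >= h/2")
    return 2.0 * math.sqrt(h * (2.0 * R_c - h))


def frontal_area(tube: TubeGeometry, h: float) -> float:
    """Streamwise-projected (frontal) area: circular segment of height h.

    Closed form ``r^2 arccos((r-h)/r) - (r-h) sqrt(2rh - h^2)`` with
    r = D/2. Note the drag table of the companion flow module uses the
    fixed reference constant 0.181 cm^2 for its drag-coefficient
    normalization (the discretized clot's projected area, ~3% below this
    closed form for the reference clot); this function returns the exact
    segment area of the idealized shape.
    """
    r = tube.radius
    if not 0.0 <= h <= tube.diameter:
        raise ValueError("h must lie in [0, D]")
    return r * r * math.acos((r - h) / r) - (r - h) * math.sqrt(2.0 * r * h - h * h)


@dataclass(frozen=True)
class ClotGeometry:
    """Clot described by height ``h`` and bottom chord ``L`` (meters)."""

    height: float
    chord_length: float
    tube: TubeGeometry = field(default_factory=TubeGeometry)

    def __post_init__(self) -> None:
        if not 0.0 < self.height < self.tube.diameter:
            raise ValueError("clot height must lie in (0, D)")
        if self.chord_length <= 0:
            raise ValueError("chord length must be positive")

    @property
    def spanwise_radius(self) -> float:
        return spanwise_cylinder_radius(self.height, self.chord_length)

    def streamwise_half_extent(self, u: float | np.ndarray) -> float | np.ndarray:
        """a(u): streamwise half-extent at height u above the tube bottom."""
        R_c = self.spanwise_radius
        d = np.asarray(u) + R_c - self.height
        return np.sqrt(np.maximum(R_c * R_c - d * d, 0.0))

    def spanwise_half_extent(self, u: float | np.ndarray) -> float | np.ndarray:
        """b(u): spanwise half-extent of the tube section at height u."""
        u = np.asarray(u)
        return np.sqrt(np.maximum(u * (self.tube.diameter - u), 0.0))

    def frontal_area(self) -> float:
        return frontal_area(self.tube, self.height)

    def volume(self, rel_tol: float = 1e-3) -> float:
        return clot_volume(self.tube, self, rel_tol=rel_tol)

    def contact_area(self, rel_tol: float = 5e-3) -> float:
        return contact_area(self.tube, self, rel_tol=rel_tol)

    def report(self) -> dict:
        """Geometry report with SI keys, JSON-serializable."""
        return {
            "D_m": self.tube.diameter,
            "h_m": self.height,
            "L_m": self.chord_length,
            "R_c_m": self.spanwise_radius,
            "volume_m3": self.volume(),
            "frontal_area_m2": self.frontal_area(),
            "contact_area_m2": self.contact_area(),
        }

    def footprint_outline(self, n: int = 181) -> np.ndarray:
        """(x, z) polyline of the wall-footprint outline, for plotting."""
        R_c = self.spanwise_radius
        r = self.tube.radius
        # wall footprint: points on the tube wall below height h and
        # inside the spanwise cylinder; parametrize by azimuth
        th_max = math.acos((r - self.height) / r)
        th = np.linspace(-th_max, th_max, n)
        u = r * (1.0 - np.cos(th))
        a = self.streamwise_half_extent(u)
        z = r * np.sin(th)
        xs = np.concatenate([a, -a[::-1], a[:1]])
        zs = np.concatenate([z, z[::-1], z[:1]])
        return np.column_stack([xs, zs])


def _converged_quad(fn: Callable[[float], float], lo: float, hi: float,
                    rel_tol: float, what: str) -> float:
    val, err = quad(fn, lo, hi, limit=400, epsabs=0.0, epsrel=min(rel_tol, 1e-8))
    if val != 0.0 and err / abs(val) > rel_tol:
        raise RuntimeError(
            f"{what} quadrature did not converge: estimate {val:g}, error {err:g}"
        )
    return val


def clot_volume(tube: TubeGeometry, clot: ClotGeometry, rel_tol: float = 1e-3) -> float:
    """Clot volume by adaptive quadrature of the rectangle sections.

    ``V = integral_0^h 4 a(u) b(u) du``; the integrand has square-root
    behavior at both endpoints, which the adaptive rule resolves. The
    error estimate is required to be below ``rel_tol`` relative.
    """
    return _converged_quad(
        lambda u: 4.0 * clot.streamwise_half_extent(u) * clot.spanwise_half_extent(u),
        0.0, clot.height, rel_tol, "volume",
    )


def contact_area(tube: TubeGeometry, clot: ClotGeometry, rel_tol: float = 5e-3) -> float:
    """Area of the tube-wall patch wetted by the clot.

    The patch is the set of wall points with height <= h lying inside the
    spanwise cylinder. Parametrizing the wall by azimuth theta from the
    bottom (height u = r(1 - cos theta)) and streamwise x, the streamwise
    extent at fixed theta is the interval |x| <= a(u(theta)), so the
    surface integral reduces to a single adaptive quadrature
    ``A_c = integral 2 a(u(theta)) r dtheta`` over |theta| <= theta_max,
    cos(theta_max) = (r - h)/r.
    """
    r = tube.radius
    th_max = math.acos((r - clot.height) / r)
    return _converged_quad(
        lambda th: 2.0 * r * float(clot.streamwise_half_extent(r * (1.0 - math.cos(th)))),
        -th_max, th_max, rel_tol, "contact area",
    )


def _max_half_extent(clot: ClotGeometry) -> float:
    """Maximum of a(u) over [0, h]: Rc at the cylinder mid-height if that
    lies inside the clot, otherwise L/2 at the tube bottom."""
    u_star = min(max(clot.height - clot.spanwise_radius, 0.0), clot.height)
    return float(clot.streamwise_half_extent(u_star))


def monte_carlo_volume(tube: TubeGeometry, clot: ClotGeometry,
                       n: int = 10**6, seed: int = 0) -> float:
    """Independent rejection-sampling oracle for :func:`clot_volume`.

    Samples uniformly in the bounding box
    ``[-a_max, a_max] x [0, h] x [-D/2, D/2]`` and counts points inside
    both constraints.
    """
    rng = np.random.default_rng(seed)
    a_max = _max_half_extent(clot)
    h, D = clot.height, tube.diameter
    x = rng.uniform(-a_max, a_max, n)
    u = rng.uniform(0.0, h, n)
    z = rng.uniform(-D / 2.0, D / 2.0, n)
    inside = (np.abs(x) <= clot.streamwise_half_extent(u)) & (
        np.abs(z) <= clot.spanwise_half_extent(u)
    )
    return float(inside.mean()) * (2.0 * a_max) * h * D


def monte_carlo_contact_area(tube: TubeGeometry, clot: ClotGeometry,
                             n: int = 10**6, seed: int = 0) -> float:
    """Surface-sampling oracle for :func:`contact_area`.

    Samples (theta, x) uniformly on the wall rectangle covering the patch
    and scales the hit fraction by the rectangle's wall area.
    """
    rng = np.random.default_rng(seed)
    r = tube.radius
    th_max = math.acos((r - clot.height) / r)
    a_max = _max_half_extent(clot)
    th = rng.uniform(-th_max, th_max, n)
    x = rng.uniform(-a_max, a_max, n)
    u = r * (1.0 - np.cos(th))
    inside = np.abs(x) <= clot.streamwise_half_extent(u)
    return float(inside.mean()) * (2.0 * th_max * r) * (2.0 * a_max)
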