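"""Sphere and prolate-spheroid geometry for vesicle morphometry.

A vesicle at rest is assumed spherical; under a uniform magnetic field a
ferrofluid-loaded vesicle elongates into a prolate spheroid with semi-axes
``a >= b`` (symmetry axis along the field).  Because the enclosed volume is
conserved during the elongation, the equal-volume rest radius is
``R0 = (a b^2)^(1/3)``, and the apparent membrane-area excess is quantified by
the dimensionless surface-area deformation

    sigma = S_ps / S_s - 1,

where ``S_s = 4 pi R0^2`` is the rest-sphere area and ``S_ps`` the prolate
surface area.  ``sigma`` is zero for a sphere and strictly increasing in the
aspect ratio ``a/b`` at fixed volume.

All lengths are micrometres unless stated otherwise; the formulas are
scale-free.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ProlateSpheroid",
    "RestSphere",
    "DeformationRecord",
    "diameter_from_area",
    "rest_radius",
    "sphere_surface",
    "prolate_surface",
    "sigma",
    "spheroid_from_sigma",
    "ellipse_axes_to_semiaxes",
]


@dataclass(frozen=True)
class ProlateSpheroid:
    """Prolate spheroid with major semi-axis ``a`` and minor semi-axis ``b`` (um)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.b > 0.0):
            raise ValueError(f"minor semi-axis must be positive, got b={self.b}")
        if self.a < self.b:
            raise ValueError(
                f"major semi-axis must satisfy a >= b (got a={self.a}, b={self.b}); "
                "swap the axes before constructing the spheroid"
            )

    @property
    def eccentricity(self) -> float:
        """Meridional eccentricity ``e`` with ``e^2 = 1 - b^2/a^2``."""
        return math.sqrt(max(0.0, 1.0 - (self.b / self.a) ** 2))

    @property
    def volume(self) -> float:
        """Enclosed volume ``4/3 pi a b^2`` (um^3)."""
        return 4.0 / 3.0 * math.pi * self.a * self.b**2

    @property
    def aspect_ratio(self) -> float:
        return self.a / self.b


@dataclass(frozen=True)
class RestSphere:
    """Equal-volume sphere of a deformed vesicle, radius ``R0`` (um)."""

    r0: float

    def __post_init__(self) -> None:
        if not (self.r0 > 0.0):
            raise ValueError(f"rest radius must be positive, got {self.r0}")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.r0**3


@dataclass(frozen=True)
class DeformationRecord:
    """Per-vesicle deformation under a named field level."""

    spheroid: ProlateSpheroid
    rest: RestSphere
    sigma: float
    field_level: str
    composition: str


def diameter_from_area(area: float | np.ndarray) -> float | np.ndarray:
    """Equivalent diameter of a circle with the given area.

    Vesicles imaged in phase contrast are treated as circles, so the measured
    cross-section area maps to a diameter ``d = 2 sqrt(area / pi)``.

    Parameters
    ----------
    area : float or ndarray
        Cross-section area in um^2 (all entries strictly positive).
    """
    arr = np.asarray(area, dtype=float)
    if np.any(~(arr > 0.0)):
        raise ValueError("area must be strictly positive")
    out = 2.0 * np.sqrt(arr / math.pi)
    return float(out) if np.isscalar(area) or arr.ndim == 0 else out


def rest_radius(s: ProlateSpheroid) -> RestSphere:
    """Equal-volume rest radius ``R0 = (a b^2)^(1/3)``."""
    return RestSphere(float(np.cbrt(s.a * s.b**2)))


def sphere_surface(r: RestSphere) -> float:
    """Surface area ``4 pi R0^2`` of the rest sphere (um^2)."""
    return 4.0 * math.pi * r.r0**2


# Below this e^2 the arcsin(e)/e form loses accuracy; switch to its series.
_E2_SERIES = 1e-10


def prolate_surface(s: ProlateSpheroid) -> float:
    """Surface area of a prolate spheroid (um^2).

    Closed form ``S = 2 pi b^2 (1 + a/(b e) * arcsin(e))`` with
    ``e^2 = 1 - b^2/a^2``.  Near the sphere (``e^2 < 1e-10``) the
    series ``arcsin(e)/e = 1 + e^2/6 + 3 e^4/40 + ...`` is used so the
    function is continuous at ``a == b``.
    """
    a, b = s.a, s.b
    e2 = 1.0 - (b / a) ** 2
    if e2 < _E2_SERIES:
        asinc = 1.0 + e2 / 6.0 + 3.0 * e2 * e2 / 40.0
        return 2.0 * math.pi * b**2 * (1.0 + (a / b) * asinc)
    e = math.sqrt(e2)
    return 2.0 * math.pi * b**2 * (1.0 + a / (b * e) * math.asin(e))


def sigma(s: ProlateSpheroid) -> float:
    """Surface-area deformation ``S_ps / S_s - 1`` (dimensionless, >= 0).

    Zero iff the spheroid is a sphere; strictly increasing in the aspect
    ratio ``a/b`` at fixed volume (isoperimetric inequality: the sphere
    minimises surface area among equal-volume shapes).
    """
    value = prolate_surface(s) / sphere_surface(rest_radius(s)) - 1.0
    # Guard tiny negative round-off at a == b.
    return max(0.0, value)


def _sigma_of_aspect(q: float) -> float:
    """sigma as a function of aspect ratio alone (unit rest radius)."""
    return sigma(ProlateSpheroid(q ** (2.0 / 3.0), q ** (-1.0 / 3.0)))


def spheroid_from_sigma(r0: float, sigma_target: float) -> ProlateSpheroid:
    """Inverse map: the volume-conserving prolate spheroid with a given sigma.

    Solves for the aspect ratio ``q = a/b`` such that the spheroid
    ``a = R0 q^(2/3)``, ``b = R0 q^(-1/3)`` (which has rest radius ``R0`` by
    construction) attains ``sigma(a, b) == sigma_target``, by monotone
    root-finding on ``q``.

    Used by the synthetic generator to turn a drawn (R0, sigma) pair into
    measurable ellipse axes.
    """
    if not (r0 > 0.0):
        raise ValueError(f"rest radius must be positive, got {r0}")
    if sigma_target < 0.0:
        raise ValueError(f"sigma must be non-negative, got {sigma_target}")
    if sigma_target == 0.0:
        return ProlateSpheroid(r0, r0)
    q_hi = 2.0
    while _sigma_of_aspect(q_hi) < sigma_target:
        q_hi *= 2.0
        if q_hi > 1e6:
            raise ValueError(f"sigma target {sigma_target} out of representable range")
    q = brentq(lambda t: _sigma_of_aspect(t) - sigma_target, 1.0, q_hi, xtol=1e-14, rtol=1e-15)
    return ProlateSpheroid(r0 * q ** (2.0 / 3.0), r0 * q ** (-1.0 / 3.0))


def ellipse_axes_to_semiaxes(major: float, minor: float) -> ProlateSpheroid:
    """Convert ImageJ full ellipse axes to spheroid semi-axes.

    ImageJ's ellipse fit reports full axis lengths (Major, Minor); the
    spheroid formulas take semi-axes, so both are halved.  If the fit
    reports ``major < minor`` (rounding artefacts), the axes are swapped
    with a warning rather than rejected.
    """
    if not (minor > 0.0 and major > 0.0):
        raise ValueError(f"axes must be positive, got major={major}, minor={minor}")
    if major < minor:
        warnings.warn(
            f"major axis {major} < minor axis {minor}; swapping", stacklevel=2
        )
        major, minor = minor, major
    return ProlateSpheroid(major / 2.0, minor / 2.0)
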