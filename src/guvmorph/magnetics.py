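"""On-axis field of cuboid permanent magnets and the two-magnet device.

The deformation setup holds two identical cuboid NdFeB magnets coaxially,
poles aligned, at a face-to-face separation ``d``; the sample sits at the
midpoint, where the superposed field is uniform over the ~1 cm^2 observation
window.  For a cuboid uniformly magnetized along its thickness ``D`` with
remanence ``Br`` and face ``L x W``, the on-axis field at distance ``z`` from
a face is the classic surface-charge closed form

    B(z) = (Br/pi) * [ atan( L W / (2 z sqrt(4 z^2 + L^2 + W^2)) )
                     - atan( L W / (2 (z+D) sqrt(4 (z+D)^2 + L^2 + W^2)) ) ]

(each atan term is 1/4 of the solid angle subtended by a charged face).  With
aligned poles the two magnets' fields add at the midpoint, so the device field
is twice the single-magnet field at half the separation.

Defaults describe the N42 15 x 15 x 8 mm magnet used in the study
(catalogue remanence taken at the upper grade limit, Br = 1.32 T); the three
named field levels H1/H2/H3 correspond to separations of 13, 10 and 4 cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "CuboidMagnet",
    "MagnetDevice",
    "axial_field",
    "field_at_center",
    "separation_for_field",
    "FIELD_LEVEL_SEPARATIONS_M",
]

MU0 = 4.0e-7 * math.pi  # vacuum permeability, T m / A

#: the study's named field levels -> face-to-face separation (m)
FIELD_LEVEL_SEPARATIONS_M = {"H1": 0.13, "H2": 0.10, "H3": 0.04}


@dataclass(frozen=True)
class CuboidMagnet:
    """Cuboid magnet: face ``length x width`` (m), ``thickness`` along the
    magnetization (m), remanence ``br`` (T).  Defaults: N42 Q-15-15-08."""

    length: float = 0.015
    width: float = 0.015
    thickness: float = 0.008
    br: float = 1.32

    def __post_init__(self) -> None:
        for name in ("length", "width", "thickness", "br"):
            if not (getattr(self, name) > 0.0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def moment(self) -> float:
        """Equivalent point-dipole moment ``Br V / mu0`` (A m^2), for far-field checks."""
        return self.br * self.length * self.width * self.thickness / MU0


@dataclass(frozen=True)
class MagnetDevice:
    """Two identical coaxial magnets, poles aligned, face-to-face ``separation`` (m)."""

    magnet: CuboidMagnet = CuboidMagnet()
    separation: float = 0.04

    def __post_init__(self) -> None:
        if not (self.separation > 0.0):
            raise ValueError(f"separation must be positive, got {self.separation}")


def axial_field(magnet: CuboidMagnet, z: float) -> float:
    """On-axis field (T) of one cuboid magnet at distance ``z`` (m) from its face.

    Positive, strictly decreasing in ``z``, and -> 0 as z -> infinity
    (asymptotically the point dipole ``mu0 m / (2 pi z^3)``).
    """
    if not (z > 0.0):
        raise ValueError(f"z must be positive, got {z}")
    L, W, D = magnet.length, magnet.width, magnet.thickness
    lw = L * W
    s2 = L * L + W * W

    def face_term(h: float) -> float:
        return math.atan(lw / (2.0 * h * math.sqrt(4.0 * h * h + s2)))

    return magnet.br / math.pi * (face_term(z) - face_term(z + D))


def field_at_center(device: MagnetDevice) -> float:
    """Midpoint field of the two-magnet device, in millitesla.

    With the poles aligned the axial fields add, so the midpoint value is
    twice the single-magnet field at ``separation / 2``.
    """
    return 2.0 * axial_field(device.magnet, device.separation / 2.0) * 1e3


_MAX_SEPARATION = 1.0  # m; beyond this the device is not physically sensible
_MIN_SEPARATION = 1e-4


def separation_for_field(magnet: CuboidMagnet, target_mt: float) -> float:
    """Face-to-face separation (m) at which the device produces ``target_mt``.

    Monotone root-finding inverse of :func:`field_at_center`; raises if the
    target lies outside the range reachable for separations in
    [0.1 mm, 1 m].
    """
    if not (target_mt > 0.0):
        raise ValueError(f"target field must be positive, got {target_mt}")
    lo, hi = _MIN_SEPARATION, _MAX_SEPARATION
    f_lo = field_at_center(MagnetDevice(magnet, lo))
    f_hi = field_at_center(MagnetDevice(magnet, hi))
    if not (f_hi <= target_mt <= f_lo):
        raise ValueError(
            f"target {target_mt} mT outside reachable range "
            f"[{f_hi:.3g}, {f_lo:.3g}] mT for separations in [{lo}, {hi}] m"
        )
    return float(
        brentq(
            lambda d: field_at_center(MagnetDevice(magnet, d)) - target_mt,
            lo,
            hi,
            xtol=1e-12,
            rtol=1e-12,
        )
    )
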