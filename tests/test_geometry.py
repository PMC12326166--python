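"""Spheroid geometry against independent numeric oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from guvmorph.geometry import (
    ProlateSpheroid,
    RestSphere,
    diameter_from_area,
    ellipse_axes_to_semiaxes,
    prolate_surface,
    rest_radius,
    sigma,
    sphere_surface,
    spheroid_from_sigma,
)


def surface_by_quadrature(a: float, b: float) -> float:
    """Oracle: surface of revolution of the ellipse about its major axis.

    Parametrize the meridian as x = a cos(t), y = b sin(t), t in [0, pi];
    S = 2 pi * int y * sqrt((dx/dt)^2 + (dy/dt)^2) dt.
    """
    integrand = lambda t: b * math.sin(t) * math.sqrt(
        (a * math.sin(t)) ** 2 + (b * math.cos(t)) ** 2
    )
    val, err = quad(integrand, 0.0, math.pi, epsabs=1e-13, epsrel=1e-12, limit=200)
    return 2.0 * math.pi * val


@pytest.mark.parametrize(
    "area,expected",
    [(math.pi, 2.0), (100 * math.pi, 20.0)],
)
def test_diameter_from_area_closed_form(area, expected):
    assert diameter_from_area(area) == pytest.approx(expected, rel=1e-12)


def test_diameter_from_area_inverts_circle_area():
    # oracle: invert d -> pi d^2 / 4 numerically
    d = diameter_from_area(113.1)
    assert math.pi * d**2 / 4.0 == pytest.approx(113.1, rel=1e-12)
    assert d == pytest.approx(12.000, abs=5e-4)


def test_diameter_from_area_rejects_nonpositive():
    with pytest.raises(ValueError):
        diameter_from_area(0.0)
    with pytest.raises(ValueError):
        diameter_from_area(-3.0)


@pytest.mark.parametrize("aspect", [1.0, 1.001, 1.5, 2.0, 5.0, 10.0, 20.0])
def test_prolate_surface_matches_quadrature(aspect):
    b = 1.3
    a = aspect * b
    assert prolate_surface(ProlateSpheroid(a, b)) == pytest.approx(
        surface_by_quadrature(a, b), rel=1e-8
    )


def test_prolate_surface_sphere_limit():
    assert prolate_surface(ProlateSpheroid(1.0, 1.0)) == pytest.approx(4 * math.pi, rel=1e-14)
    # continuity across the series/closed-form switch
    assert prolate_surface(ProlateSpheroid(1.0 + 1e-12, 1.0)) == pytest.approx(
        4 * math.pi, abs=1e-9
    )


def test_prolate_surface_known_value():
    # frozen from the quadrature oracle at a=2, b=1
    assert prolate_surface(ProlateSpheroid(2.0, 1.0)) == pytest.approx(21.4784353, rel=1e-7)


def test_spheroid_requires_major_not_smaller():
    with pytest.raises(ValueError, match="swap"):
        ProlateSpheroid(1.0, 2.0)
    with pytest.raises(ValueError):
        ProlateSpheroid(1.0, 0.0)


@given(
    b=st.floats(0.5, 50.0),
    aspect=st.floats(1.0, 20.0),
)
def test_volume_conservation(b, aspect):
    s = ProlateSpheroid(aspect * b, b)
    r = rest_radius(s)
    assert abs(s.volume - r.volume) / s.volume < 1e-12


def test_rest_radius_examples():
    assert rest_radius(ProlateSpheroid(5.0, 5.0)).r0 == pytest.approx(5.0, rel=1e-15)
    assert rest_radius(ProlateSpheroid(4.0, 1.0)).r0 == pytest.approx(4.0 ** (1 / 3), rel=1e-12)


def test_sphere_surface_matches_degenerate_spheroid():
    r0 = 3.7
    assert sphere_surface(RestSphere(r0)) == pytest.approx(
        surface_by_quadrature(r0, r0), rel=1e-10
    )
    assert sphere_surface(RestSphere(1.0)) == pytest.approx(4 * math.pi, rel=1e-15)


def test_sigma_zero_iff_sphere():
    assert sigma(ProlateSpheroid(3.0, 3.0)) == 0.0
    assert sigma(ProlateSpheroid(3.0 * (1 + 1e-10), 3.0)) == pytest.approx(0.0, abs=1e-10)
    assert sigma(ProlateSpheroid(3.3, 3.0)) > 0.0


def test_sigma_known_value():
    # frozen from the two surface oracles at a=2, b=1
    assert sigma(ProlateSpheroid(2.0, 1.0)) == pytest.approx(0.0767283, abs=1e-6)


def test_sigma_strictly_increasing_in_aspect_ratio():
    r0 = 7.0
    aspects = np.linspace(1.0, 6.0, 40)
    vals = [sigma(ProlateSpheroid(r0 * q ** (2 / 3), r0 * q ** (-1 / 3))) for q in aspects]
    assert np.all(np.diff(vals) > 0)


@pytest.mark.parametrize("target", [0.01, 0.1, 0.4])
def test_spheroid_from_sigma_round_trip(target):
    s = spheroid_from_sigma(10.0, target)
    assert sigma(s) == pytest.approx(target, abs=1e-8)
    assert rest_radius(s).r0 == pytest.approx(10.0, rel=1e-10)


def test_spheroid_from_sigma_degenerate_and_errors():
    s = spheroid_from_sigma(4.2, 0.0)
    assert s.a == s.b == 4.2
    with pytest.raises(ValueError):
        spheroid_from_sigma(4.2, -0.1)


def test_spheroid_from_sigma_scales_linearly_in_r0():
    s1 = spheroid_from_sigma(1.0, 0.2)
    s5 = spheroid_from_sigma(5.0, 0.2)
    assert s5.a == pytest.approx(5 * s1.a, rel=1e-9)
    assert s5.b == pytest.approx(5 * s1.b, rel=1e-9)


def test_ellipse_axes_halved_and_swapped():
    s = ellipse_axes_to_semiaxes(24.0, 20.0)
    assert (s.a, s.b) == (12.0, 10.0)
    sphere = ellipse_axes_to_semiaxes(10.0, 10.0)
    assert sphere.a == sphere.b == 5.0
    with pytest.warns(UserWarning, match="swap"):
        swapped = ellipse_axes_to_semiaxes(20.0, 24.0)
    assert (swapped.a, swapped.b) == (12.0, 10.0)
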