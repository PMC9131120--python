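"""Scalar optics of a 2-D hexagonally packed colony.

Two relations carry the whole optical analysis:

1.  The angular shift of the specular reflection peak.  A photonic slab
    with normal-incidence reflection peak ``lambda_p`` and effective
    (average) refractive index ``n_avg`` shifts its specular peak to

        lambda_s = lambda_p * cos(theta_2),
        theta_2  = arcsin(sin(theta_in) / n_avg)            (Snell's law)

    where ``theta_in`` is the incidence angle.  Fitting ``lambda_s``
    versus ``theta_in`` yields ``n_avg``.

2.  The grating equation for the in-plane period ``d`` of the hexagonal
    packing:

        theta_m = arcsin(m * lambda / d - sin(theta_i)),

    which locates the ``m``-th diffraction order of wavelength
    ``lambda`` for incidence ``theta_i``.

Angle frames
------------
The grating equation above is written in its textbook frame: incidence
``theta_i`` positive, zero order (mirror) at ``-theta_i``.  Goniometer
maps use the lab frame, where the illumination angle is negative (e.g.
-60 deg) and the specular reflection appears at ``-theta_illum``; lab
detection angles are the negative of the textbook ``theta_m`` evaluated
at ``theta_i = -theta_illum``.  :func:`diffraction_angle` works in the
textbook frame, :func:`detection_angle` in the lab frame.

Crystalline domains need not lie parallel to the agar surface.  A tilt
``alpha`` (deg) rotates the domain normal within the scattering plane;
diffraction then happens in the tilted frame (incidence reduced by
``alpha``) and the outgoing beam is rotated back.  For the zero order
this is the familiar mirror result: the beam moves by exactly
``2 * alpha``.

All functions here are pure and operate on scalars in degrees.
"""

from __future__ import annotations

import math

__all__ = [
    "EVANESCENT",
    "specular_angle_of",
    "specular_shift",
    "diffraction_angle",
    "diffraction_wavelength",
    "detection_angle",
    "ridge_wavelength",
]

#: Distinguished return value for non-propagating diffraction orders.
EVANESCENT = "evanescent"


def _check_angle(theta: float, name: str) -> None:
    if not -90.0 < theta < 90.0:
        raise ValueError(f"{name} must lie in (-90, 90) deg, got {theta}")


def specular_angle_of(theta: float) -> float:
    """Mirror direction of an angle: specular detection of illumination ``theta``."""
    _check_angle(theta, "theta")
    return -theta


def specular_shift(lambda_p: float, n_avg: float, theta_in: float) -> float:
    """Specular peak wavelength at oblique incidence.

    Parameters
    ----------
    lambda_p : float
        Peak wavelength at normal incidence (nm).
    n_avg : float
        Effective refractive index of the colony (>= 1).
    theta_in : float
        Incidence angle (deg), ``|theta_in| < 90``.

    Returns
    -------
    float
        Shifted peak wavelength ``lambda_s`` (nm); equals ``lambda_p``
        at normal incidence and decreases with ``|theta_in|``.
    """
    if n_avg < 1.0:
        raise ValueError(f"n_avg must be >= 1, got {n_avg}")
    if lambda_p <= 0:
        raise ValueError("lambda_p must be positive")
    _check_angle(theta_in, "theta_in")
    theta_2 = math.asin(math.sin(math.radians(theta_in)) / n_avg)
    return lambda_p * math.cos(theta_2)


def diffraction_angle(
    d: float,
    m: int,
    lam: float,
    theta_i: float,
    tilt_alpha: float = 0.0,
):
    """Diffracted angle of order ``m`` in the textbook grating frame.

    For an untilted domain this is ``arcsin(m*lam/d - sin(theta_i))``.
    A domain tilted by ``tilt_alpha`` sees incidence
    ``theta_i - tilt_alpha``; the diffracted beam is computed in that
    frame and rotated back by ``+tilt_alpha``.  For ``m = 0`` the result
    reduces to ``-theta_i + 2*tilt_alpha`` (mirror law).

    Returns
    -------
    float or str
        Diffracted angle (deg), or :data:`EVANESCENT` when the order
        does not propagate.
    """
    if d <= 0:
        raise ValueError("lattice constant d must be positive")
    if lam <= 0:
        raise ValueError("wavelength must be positive")
    _check_angle(theta_i, "theta_i")
    s = m * lam / d - math.sin(math.radians(theta_i - tilt_alpha))
    if abs(s) > 1.0:
        return EVANESCENT
    return math.degrees(math.asin(s)) + tilt_alpha


def diffraction_wavelength(
    d: float,
    m: int,
    theta_m: float,
    theta_i: float,
    tilt_alpha: float = 0.0,
) -> float:
    """Wavelength diffracted into ``theta_m`` — exact inverse of
    :func:`diffraction_angle` for ``m != 0``."""
    if m == 0:
        raise ValueError("the zero order has no wavelength selectivity")
    if d <= 0:
        raise ValueError("lattice constant d must be positive")
    a = math.radians(theta_m - tilt_alpha)
    b = math.radians(theta_i - tilt_alpha)
    return d * (math.sin(a) + math.sin(b)) / m


def detection_angle(
    d: float,
    m: int,
    lam: float,
    theta_illum: float,
    tilt_alpha: float = 0.0,
):
    """Lab-frame detection angle of order ``m`` for illumination ``theta_illum``.

    ``theta_illum`` is negative by convention; the zero order (specular)
    of an untilted domain lands at ``-theta_illum``.  A positive
    ``tilt_alpha`` rotates the domain normal towards the detector side,
    moving the specular direction to ``-theta_illum + 2*tilt_alpha``.

    Returns the detection angle (deg) or :data:`EVANESCENT`.
    """
    theta = diffraction_angle(d, m, lam, -theta_illum, -tilt_alpha)
    if theta == EVANESCENT:
        return EVANESCENT
    return -theta


def ridge_wavelength(
    d: float,
    m: int,
    theta_det: float,
    theta_illum: float,
    tilt_alpha: float = 0.0,
) -> float:
    """Wavelength reaching lab detection angle ``theta_det`` in order ``m``.

    Exact inverse of :func:`detection_angle`; the (lambda, theta_det)
    curve it traces is the diffraction ridge seen in goniometer maps.
    """
    return diffraction_wavelength(d, m, -theta_det, -theta_illum, -tilt_alpha)
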