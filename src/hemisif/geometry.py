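"""Closed-form footprint geometry of hemispherical cosine-corrected observations.

For a downward-looking cosine-corrected foreoptic over a homogeneous Lambertian
surface, the irradiance collected from view zenith angles up to theta_max is

    E(theta_max) = 2 pi L T * integral_0^theta_max cos(theta) sin(theta) dtheta
                 = pi L T sin^2(theta_max),

so the *fraction* of the full hemispherical signal contributed by the cone
theta <= theta_max is sin^2(theta_max), independent of the radiance level.
Everything in this module follows from that identity plus plane trigonometry:
per-ring contributions, the inverse (zenith limit for a target fraction), the
ground footprint radius H tan(theta_max) for a sensor at height H, and the
angular width subtended by an obstacle (e.g. the tower body) below the sensor.

Angle convention: all public angles are in DEGREES, and a "zenith limit" is the
half-cone view zenith angle. Instrument spec sheets often quote the full cone
opening (e.g. a 25 deg conical foreoptic); convert with
:func:`half_cone_from_full_fov`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "cumulative_fraction",
    "ring_contribution",
    "ring_table",
    "zenith_for_fraction",
    "peak_contribution_zenith",
    "ground_radius",
    "obstruction_angle",
    "half_cone_from_full_fov",
    "FootprintSummary",
]


def _check_range(value: float, lo: float, hi: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or value < lo or value > hi:
        raise ValueError(f"{name} must lie in [{lo}, {hi}], got {value!r}")
    return value


def cumulative_fraction(zenith_limit: float) -> float:
    """Fraction of hemispherical cosine-weighted irradiance within a zenith cone.

    Returns sin^2(zenith_limit); 0 at nadir-only, 1 for the full hemisphere,
    0.9045 at the 72 deg limit that bounds ~90% of the signal.
    """
    z = _check_range(zenith_limit, 0.0, 90.0, "zenith_limit")
    return float(np.sin(np.radians(z)) ** 2)


def ring_contribution(zenith_lo: float, zenith_hi: float) -> float:
    """Fractional contribution of the annular zone [zenith_lo, zenith_hi]."""
    lo = _check_range(zenith_lo, 0.0, 90.0, "zenith_lo")
    hi = _check_range(zenith_hi, 0.0, 90.0, "zenith_hi")
    if lo >= hi:
        raise ValueError("require zenith_lo < zenith_hi")
    return cumulative_fraction(hi) - cumulative_fraction(lo)


def ring_table(zenith_step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Ring centres (deg) and per-ring fractions over [0, 90] at `zenith_step`."""
    if zenith_step <= 0 or zenith_step > 90:
        raise ValueError("zenith_step must lie in (0, 90]")
    edges = np.arange(0.0, 90.0 + zenith_step / 2, zenith_step)
    if edges[-1] > 90.0:
        edges[-1] = 90.0
    s2 = np.sin(np.radians(edges)) ** 2
    return 0.5 * (edges[:-1] + edges[1:]), np.diff(s2)


def zenith_for_fraction(p: float) -> float:
    """Zenith limit (deg) whose cone contributes the fraction `p`; arcsin(sqrt(p))."""
    p = _check_range(p, 0.0, 1.0, "fraction")
    return float(np.degrees(np.arcsin(np.sqrt(p))))


def peak_contribution_zenith(zenith_step: float | None = None) -> float:
    """View zenith angle (deg) of maximal per-ring contribution.

    The contribution density cos(theta) sin(theta) = sin(2 theta)/2 peaks at
    45 deg. With `zenith_step` given, the argmax is located numerically on a
    grid of that spacing (returns the grid angle of peak density).
    """
    if zenith_step is None:
        return 45.0
    if zenith_step <= 0:
        raise ValueError("zenith_step must be positive")
    theta = np.arange(0.0, 90.0 + zenith_step / 2, zenith_step)
    density = np.cos(np.radians(theta)) * np.sin(np.radians(theta))
    return float(theta[np.argmax(density)])


def ground_radius(sensor_height: float, zenith_limit: float) -> float:
    """Radius (m) on the ground of the cone with the given zenith limit."""
    if sensor_height <= 0:
        raise ValueError("sensor_height must be positive")
    z = _check_range(zenith_limit, 0.0, 90.0, "zenith_limit")
    if z >= 90.0:
        raise ValueError("zenith_limit of 90 deg gives an unbounded footprint")
    return float(sensor_height * np.tan(np.radians(z)))


def obstruction_angle(obstacle_diameter: float, sensor_height: float) -> float:
    """Full angular width (deg) of an obstacle of given ground-projected diameter.

    Seen from the sensor straight down: 2 atan(d / 2H). A 5 m tower projection
    under a 20 m sensor blocks 14.25 deg of the 180 deg field (~8%).
    """
    if sensor_height <= 0:
        raise ValueError("sensor_height must be positive")
    if obstacle_diameter < 0:
        raise ValueError("obstacle_diameter must be non-negative")
    return float(np.degrees(2.0 * np.arctan(obstacle_diameter / (2.0 * sensor_height))))


def half_cone_from_full_fov(full_fov: float) -> float:
    """Half-cone zenith limit (deg) for a full-cone instrument FOV."""
    f = _check_range(full_fov, 0.0, 180.0, "full_fov")
    return f / 2.0


@dataclass(frozen=True)
class FootprintSummary:
    """Zenith limit, captured fraction and ground radius for one sensor height."""

    zenith_limit: float
    cumulative_fraction: float
    ground_radius: float
    sensor_height: float

    @classmethod
    def from_zenith_limit(cls, sensor_height: float, zenith_limit: float) -> "FootprintSummary":
        return cls(
            zenith_limit=float(zenith_limit),
            cumulative_fraction=cumulative_fraction(zenith_limit),
            ground_radius=ground_radius(sensor_height, zenith_limit),
            sensor_height=float(sensor_height),
        )

    @classmethod
    def from_fraction(cls, sensor_height: float, fraction: float) -> "FootprintSummary":
        return cls.from_zenith_limit(sensor_height, zenith_for_fraction(fraction))
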