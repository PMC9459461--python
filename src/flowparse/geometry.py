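"""Planar angle conventions shared by every module.

The whole package works in screen coordinates with x rightward and
y upward, and measures directions in **degrees clockwise from
vertical-up**.  A direction ``theta`` therefore maps to the unit vector
``(sin theta, cos theta)``: 0 deg is straight up, 90 deg is rightward.
Stripe orientations of grating carriers live on [0, 180).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "direction_to_vector",
    "vector_to_direction",
    "wrap_direction",
    "wrap_signed",
    "drift_axis",
]

_AXIS_EPS = 1e-12


def wrap_direction(theta: float) -> float:
    """Normalize a direction to [0, 360)."""
    return float(np.mod(theta, 360.0))


def wrap_signed(theta: float) -> float:
    """Wrap an angular difference to (-180, 180]."""
    t = np.mod(theta, 360.0)
    return float(t - 360.0 if t > 180.0 else t)


def direction_to_vector(theta_deg: float, speed: float = 1.0) -> np.ndarray:
    """Velocity vector for a direction given clockwise from vertical-up."""
    t = np.deg2rad(theta_deg)
    return speed * np.array([np.sin(t), np.cos(t)])


def vector_to_direction(v) -> float:
    """Direction of a nonzero vector, in degrees clockwise from vertical-up.

    Returned in (-180, 180]; raises ``ValueError`` on the zero vector,
    whose direction is undefined.
    """
    v = np.asarray(v, dtype=float)
    if np.hypot(v[0], v[1]) == 0.0:
        raise ValueError("direction of the zero vector is undefined")
    return float(np.rad2deg(np.arctan2(v[0], v[1])))


def drift_axis(orientation_deg: float) -> np.ndarray:
    """Unit drift axis for a carrier of given stripe orientation.

    Drift is orthogonal to the stripes, i.e. along ``orientation + 90``
    deg.  Because a grating drifting at rate +r along n-hat is identical
    to one drifting at -r along -n-hat, the axis is canonicalized to the
    half-plane with positive x (ties broken toward positive y) so that
    signed drift rates are reproducible.
    """
    if not 0.0 <= orientation_deg < 180.0:
        raise ValueError(f"orientation must lie in [0, 180), got {orientation_deg}")
    n = direction_to_vector(orientation_deg + 90.0)
    if n[0] < -_AXIS_EPS or (abs(n[0]) <= _AXIS_EPS and n[1] < 0):
        n = -n
    # snap near-zero components so cardinal axes are exact
    n[np.abs(n) <= _AXIS_EPS] = 0.0
    return n / np.hypot(n[0], n[1])
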