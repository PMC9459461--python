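"""Synthetic flow-parsing observer.

The observer perceives target motion as ``p = t - beta * b``: the
actual target velocity minus a weighted copy of the background
velocity.  ``beta`` is the flow-parsing gain (1 = complete background
subtraction, 0 = none); the illusory deviation of the perceived target
direction away from the background direction is induced motion.

Judgments are binary (clockwise / anticlockwise of vertical).  A
constant error in perceived vertical (``bias``) rotates the judged
target direction before the background subtraction, and angular
Gaussian noise acts on the resulting perceived direction before the
sign decision, so the psychometric function over physical target
direction is monotone and crosses 0.5 exactly at the flow-parsing
point of subjective equality (PSE); lapses replace the judgment with a
coin flip.

The observer deliberately ignores element-level detail (spatial
frequency, orientation content, 1D/2D element type, layout): it
consumes only the integrated global motions.  Simulated condition
contrasts therefore differ only by sampling noise, by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .geometry import direction_to_vector, vector_to_direction

__all__ = [
    "ObserverParams",
    "PerceivedMotion",
    "NoSolutionError",
    "CLOCKWISE",
    "ANTICLOCKWISE",
    "perceived_motion",
    "respond",
    "pse_closed_form",
]

CLOCKWISE = "clockwise"
ANTICLOCKWISE = "anticlockwise"

_ZERO_SPEED = 1e-12


class NoSolutionError(ValueError):
    """The requested perceived-vertical crossing does not exist."""


@dataclass(frozen=True)
class ObserverParams:
    """Flow-parsing observer parameters.

    beta : weight on the subtracted background velocity (dimensionless)
    bias : constant error in perceived vertical, degrees (added to the
        perceived direction before the sign decision)
    noise_sd : SD of Gaussian angular decision noise, degrees
    lapse : probability of a stimulus-independent random response
    """

    beta: float
    bias: float = 0.0
    noise_sd: float = 0.0
    lapse: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ObserverParams":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class PerceivedMotion:
    """Perceived target velocity and its direction (None when p = 0)."""

    vector: tuple[float, float]
    direction: float | None

    @property
    def defined(self) -> bool:
        return self.direction is not None


def perceived_motion(t, b, beta: float) -> PerceivedMotion:
    """Apply the flow-parsing rule ``p = t - beta * b``.

    ``t`` and ``b`` are 2-D velocity vectors (deg/s).  When the
    subtraction cancels exactly, the perceived direction is undefined
    and downstream judgments fall back to a random response.
    """
    p = np.asarray(t, dtype=float) - beta * np.asarray(b, dtype=float)
    if np.hypot(p[0], p[1]) < _ZERO_SPEED:
        return PerceivedMotion(vector=(p[0], p[1]), direction=None)
    return PerceivedMotion(vector=(p[0], p[1]), direction=vector_to_direction(p))


def respond(
    theta_t: float,
    theta_b: float,
    speeds: tuple[float, float],
    params: ObserverParams,
    rng: np.random.Generator,
) -> str:
    """One clockwise/anticlockwise judgment of target direction.

    With probability ``lapse`` the response is a coin flip; otherwise
    the observer responds clockwise iff
    ``direction(p) + N(0, noise_sd) > 0``, where ``p`` is computed from
    the target direction as misperceived under the constant vertical
    error (``theta_t + bias``).  Placing the bias on the target
    judgment, upstream of the background subtraction, makes the
    psychometric function cross 0.5 exactly at
    :func:`pse_closed_form` for every bias.
    """
    s_t, s_b = speeds
    if s_t <= 0 or s_b <= 0:
        raise ValueError("speeds must be positive")
    if params.lapse > 0 and rng.random() < params.lapse:
        return CLOCKWISE if rng.random() < 0.5 else ANTICLOCKWISE
    p = perceived_motion(
        direction_to_vector(theta_t + params.bias, s_t),
        direction_to_vector(theta_b, s_b),
        params.beta,
    )
    if not p.defined:
        return CLOCKWISE if rng.random() < 0.5 else ANTICLOCKWISE
    noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
    return CLOCKWISE if p.direction + noise > 0 else ANTICLOCKWISE


def pse_closed_form(
    beta: float,
    s_t: float,
    s_b: float,
    theta_b: float,
    bias: float = 0.0,
) -> float:
    """Physical target direction judged vertical, in closed form.

    Setting the horizontal component of ``p = t - beta*b`` to zero
    gives ``sin(theta_pse) = beta * (s_b / s_t) * sin(theta_b)``, so the
    PSE is ``arcsin(beta * (s_b/s_t) * sin(theta_b)) - bias`` degrees.
    Raises :class:`NoSolutionError` when the arcsine argument leaves
    [-1, 1] (background influence too strong for any vertical percept).
    """
    arg = beta * (s_b / s_t) * np.sin(np.deg2rad(theta_b))
    if abs(arg) > 1.0:
        raise NoSolutionError(
            f"no target direction is perceived vertical (arcsin argument {arg:.3f})"
        )
    return float(np.rad2deg(np.arcsin(arg))) - bias
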