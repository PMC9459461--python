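"""Local-to-global motion integration.

Two integration rules, matching how the visual system is thought to
combine local signals: 1-D (grating) signals, each of which constrains
the global velocity to a line ``v . n = r`` (the aperture problem), are
combined by intersection of constraints (IOC); unambiguous 2-D (plaid)
signals are combined by vector averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import drift_axis

__all__ = [
    "LocalConstraint",
    "UnderdeterminedError",
    "IllConditionedWarning",
    "ioc_solve",
    "vector_average",
    "constraints_from_spec",
    "constraints_from_manifest",
]

RCOND_WARN_THRESHOLD = 1e-8


class UnderdeterminedError(ValueError):
    """Fewer than two distinct constraint orientations: no unique IOC."""


class IllConditionedWarning(UserWarning):
    """Constraint axes are distinct but nearly parallel."""


@dataclass(frozen=True)
class LocalConstraint:
    """One aperture-limited motion signal: the line ``v . axis = rate``."""

    axis: tuple[float, float]
    rate: float

    def __post_init__(self):
        norm = float(np.hypot(*self.axis))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"constraint axis must be a unit vector, |axis|={norm}")

    @classmethod
    def from_orientation(cls, orientation: float, rate: float) -> "LocalConstraint":
        n = drift_axis(orientation)
        return cls(axis=(float(n[0]), float(n[1])), rate=float(rate))


def ioc_solve(constraints: list[LocalConstraint]) -> np.ndarray:
    """Least-squares intersection-of-constraints velocity.

    Minimizes ``sum_i (v . n_i - r_i)^2`` over 2-D velocities ``v``,
    which is the exact intersection when the constraint lines are
    consistent.  Raises :class:`UnderdeterminedError` when the axes do
    not span the plane; emits :class:`IllConditionedWarning` when they
    span it only marginally (reciprocal condition number below 1e-8).
    """
    if len(constraints) < 2:
        raise UnderdeterminedError(
            "need at least two constraints with distinct orientations"
        )
    n = np.array([c.axis for c in constraints], dtype=float)
    r = np.array([c.rate for c in constraints], dtype=float)
    s = np.linalg.svd(n, compute_uv=False)
    if s[-1] <= 1e-12 * s[0]:
        raise UnderdeterminedError(
            "constraint axes are parallel; the IOC velocity is not unique"
        )
    if s[-1] / s[0] < RCOND_WARN_THRESHOLD:
        warnings.warn(
            "constraint set is nearly parallel; IOC solution is ill-conditioned",
            IllConditionedWarning,
            stacklevel=2,
        )
    v, *_ = np.linalg.lstsq(n, r, rcond=None)
    return v


def vector_average(velocities) -> np.ndarray:
    """Arithmetic mean of 2-D velocity vectors (2-D signal integration)."""
    v = np.asarray(velocities, dtype=float)
    if v.size == 0:
        raise ValueError("cannot average an empty velocity list")
    return v.reshape(-1, 2).mean(axis=0)


def constraints_from_spec(spec, owner: str = "background") -> list[LocalConstraint]:
    """Constraints carried by one object's elements in a stimulus spec."""
    out = []
    for el in spec.elements:
        if el.owner != owner:
            continue
        for ori, rate in zip(el.component_orientations, el.drift_rates):
            out.append(LocalConstraint.from_orientation(ori, rate))
    return out


def constraints_from_manifest(
    manifest: pd.DataFrame | str, owner: str = "background"
) -> list[LocalConstraint]:
    """Read constraints from an element-manifest table or CSV path."""
    df = pd.read_csv(manifest) if isinstance(manifest, str) else manifest
    out = []
    for row in df.itertuples(index=False):
        if row.owner != owner:
            continue
        out.append(LocalConstraint.from_orientation(row.orientation, row.drift_rate_1))
        if row.kind == "plaid" and np.isfinite(row.drift_rate_2):
            out.append(
                LocalConstraint.from_orientation(
                    (row.orientation + 90.0) % 180.0, row.drift_rate_2
                )
            )
    return out
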