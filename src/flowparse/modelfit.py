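"""Fit the flow-parsing model to PSE-versus-background-direction curves.

The vector model ``p = t - beta * b`` reduces, at the perceived-vertical
crossing, to the scalar relation

    PSE(theta_b) = arcsin(beta * (s_b / s_t) * sin(theta_b)) - offset

where ``beta`` is the flow-parsing gain, ``s_b / s_t`` the
background/target speed ratio and ``offset`` absorbs constant errors in
perceived vertical.  :class:`FlowParsingRegression` fits (beta, offset)
by bounded nonlinear least squares with a multi-start over beta; the
predicted repulsion is maximal when the background moves orthogonally
to the (perceived) target direction, i.e. at 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .observer import NoSolutionError

__all__ = [
    "FitResult",
    "FlowParsingRegression",
    "fit_flow_parsing",
    "predict_deviation",
    "predict_peak",
    "peak_by_grid_search",
]

BETA_STARTS = tuple(np.round(np.arange(0.05, 1.0, 0.10), 2))  # 0.05 .. 0.95
_ARCSIN_MARGIN = 1.0 - 1e-12


def predict_deviation(beta: float, speed_ratio: float, theta_b) -> np.ndarray | float:
    """Model deviation of the subjectively-vertical target direction.

    ``arcsin(beta * speed_ratio * sin(theta_b))`` in degrees; raises
    :class:`NoSolutionError` if the argument leaves [-1, 1].
    """
    arg = beta * speed_ratio * np.sin(np.deg2rad(theta_b))
    if np.any(np.abs(arg) > 1.0):
        raise NoSolutionError("|beta * speed_ratio * sin(theta_b)| exceeds 1")
    out = np.rad2deg(np.arcsin(arg))
    return float(out) if np.isscalar(theta_b) else out


def predict_peak(beta: float, speed_ratio: float = 1.0) -> float:
    """Background direction (deg, relative to the perceived target
    direction) of maximal predicted deviation on [0, 180].

    ``sin`` peaks at 90 deg and ``arcsin`` is increasing, so the
    repulsion maximum sits at 90 deg for any gain in (0, 1].
    """
    if not 0.0 < beta * speed_ratio <= 1.0:
        raise ValueError("peak undefined unless beta * speed_ratio is in (0, 1]")
    return 90.0


def peak_by_grid_search(
    beta: float, speed_ratio: float = 1.0, resolution: float = 0.1
) -> float:
    """Brute-force argmax of |deviation| over [0, 180] deg."""
    if beta * speed_ratio <= 0:
        raise ValueError("peak undefined for zero gain")
    grid = np.arange(0.0, 180.0 + resolution / 2.0, resolution)
    dev = np.abs(predict_deviation(beta, speed_ratio, grid))
    return float(grid[int(np.argmax(dev))])


@dataclass
class FitResult:
    """Fitted flow-parsing parameters for one PSE curve."""

    beta_hat: float
    offset_hat: float
    r_squared: float
    residuals: np.ndarray
    speed_ratio: float
    n_points: int
    r_squared_degenerate: bool = False

    def predict(self, theta_b) -> np.ndarray:
        return predict_deviation(self.beta_hat, self.speed_ratio, theta_b) - self.offset_hat


class FlowParsingRegression(BaseEstimator, RegressorMixin):
    """Least-squares fit of ``PSE = arcsin(beta * r * sin(theta_b)) - offset``.

    Parameters
    ----------
    speed_ratio : float, default 1.0
        Background/target speed ratio ``r = s_b / s_t``.
    beta_starts : tuple of float
        Multi-start initial values for the gain.

    Attributes (after ``fit``)
    --------------------------
    beta_ : fitted flow-parsing gain, constrained to keep the arcsine
        argument in [-1, 1] over all directions.
    offset_ : fitted constant error in perceived vertical (deg).
    r_squared_ : ``1 - SS_res / SS_tot`` (NaN with
        ``r_squared_degenerate_`` set when the data have no variance).
    residuals_ : per-point residuals (deg).
    """

    def __init__(self, speed_ratio: float = 1.0, beta_starts: tuple = BETA_STARTS):
        self.speed_ratio = speed_ratio
        self.beta_starts = beta_starts

    def fit(self, X, y):
        theta_b = np.asarray(X, dtype=float).reshape(-1)
        pse = np.asarray(y, dtype=float).reshape(-1)
        if theta_b.size != pse.size:
            raise ValueError("X and y must have the same length")
        if not np.all(np.isfinite(theta_b)) or not np.all(np.isfinite(pse)):
            raise ValueError("inputs must be finite")
        if np.unique(theta_b).size < 3:
            raise ValueError("need at least 3 distinct background directions")
        r = float(self.speed_ratio)
        if r <= 0:
            raise ValueError("speed_ratio must be positive")
        # keep |beta * r * sin(theta)| <= 1 for every direction
        beta_max = _ARCSIN_MARGIN / r
        s = np.sin(np.deg2rad(theta_b))

        def residual(params):
            beta, offset = params
            return np.rad2deg(np.arcsin(np.clip(beta * r * s, -1.0, 1.0))) - offset - pse

        best = None
        for beta0 in self.beta_starts:
            beta0 = min(max(beta0, 0.0), beta_max)
            sol = least_squares(
                residual,
                x0=[beta0, float(np.mean(-pse))],
                bounds=([0.0, -np.inf], [beta_max, np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success:
            raise RuntimeError(
                "flow-parsing fit did not converge; best iterate: "
                f"{None if best is None else best.x}"
            )
        self.beta_, self.offset_ = (float(best.x[0]), float(best.x[1]))
        self.residuals_ = -residual(best.x)
        ss_res = float(np.sum(self.residuals_**2))
        ss_tot = float(np.sum((pse - pse.mean()) ** 2))
        self.r_squared_degenerate_ = ss_tot == 0.0
        self.r_squared_ = np.nan if self.r_squared_degenerate_ else 1.0 - ss_res / ss_tot
        self.n_points_ = int(pse.size)
        return self

    def predict(self, X):
        theta_b = np.asarray(X, dtype=float).reshape(-1)
        arg = np.clip(self.beta_ * self.speed_ratio * np.sin(np.deg2rad(theta_b)), -1, 1)
        return np.rad2deg(np.arcsin(arg)) - self.offset_


def fit_flow_parsing(curve, speed_ratio: float = 1.0) -> FitResult:
    """Fit the flow-parsing model to a PSE curve.

    ``curve`` is either a DataFrame with ``background_direction`` and
    ``pse`` columns (e.g. an experiment module output) or a pair of
    arrays ``(theta_b, pse)``.
    """
    if isinstance(curve, pd.DataFrame):
        theta_b = curve["background_direction"].to_numpy(dtype=float)
        pse = curve["pse"].to_numpy(dtype=float)
    else:
        theta_b, pse = (np.asarray(a, dtype=float) for a in curve)
    est = FlowParsingRegression(speed_ratio=speed_ratio).fit(theta_b, pse)
    return FitResult(
        beta_hat=est.beta_,
        offset_hat=est.offset_,
        r_squared=est.r_squared_,
        residuals=est.residuals_,
        speed_ratio=speed_ratio,
        n_points=est.n_points_,
        r_squared_degenerate=est.r_squared_degenerate_,
    )
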