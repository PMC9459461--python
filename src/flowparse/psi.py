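"""Psi adaptive Bayesian estimation of the point of subjective vertical.

The Psi method maintains a posterior over psychometric-function
parameters (PSE ``mu`` and slope ``sigma`` of a cumulative Gaussian
with a small fixed lapse) and, on every trial, presents the candidate
stimulus that minimizes the expected posterior entropy over the two
possible responses.  Here the stimulus is the physical target
direction (degrees clockwise of vertical) and the response is the
observer's clockwise/anticlockwise judgment.

Implementation note: minimizing expected posterior entropy is
algebraically identical to maximizing the mutual information between
the response and the parameters, ``H(p(r|x)) - E_theta[H(p(r|x,
theta))]``; the conditional-entropy term depends only on the fixed
likelihood table and is precomputed, so each trial costs two
matrix-vector products.  Posterior accumulation is carried in log
space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr

from .observer import ANTICLOCKWISE, CLOCKWISE

__all__ = [
    "PsychometricParams",
    "PsiState",
    "NotReadyError",
    "psi_init",
    "psi_select_stimulus",
    "psi_update",
    "psi_estimate",
    "posterior_entropy",
    "default_mu_grid",
    "default_sigma_grid",
    "make_default_state",
    "DEFAULT_LAPSE",
    "DEFAULT_N_TRIALS",
]

DEFAULT_LAPSE = 0.02
DEFAULT_N_TRIALS = 75


class NotReadyError(RuntimeError):
    """An estimate was requested before any trial was run."""


@dataclass(frozen=True)
class PsychometricParams:
    """Cumulative-Gaussian psychometric parameters.

    ``P(clockwise | theta) = lapse/2 + (1 - lapse) * Phi((theta - mu) / sigma)``
    """

    mu: float
    sigma: float
    lapse: float = DEFAULT_LAPSE

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")

    def p_clockwise(self, theta) -> np.ndarray:
        z = (np.asarray(theta, dtype=float) - self.mu) / self.sigma
        return self.lapse / 2.0 + (1.0 - self.lapse) * ndtr(z)


def default_mu_grid() -> np.ndarray:
    """PSE grid: -40..40 deg in 1 deg steps."""
    return np.arange(-40.0, 41.0)


def default_sigma_grid() -> np.ndarray:
    """Slope grid: 20 log-spaced levels from 0.5 to 20 deg."""
    return np.geomspace(0.5, 20.0, 20)


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0) - np.where(
            p < 1, (1.0 - p) * np.log1p(-p), 0.0
        )
    return h


@dataclass
class PsiState:
    """Posterior grid, candidate set and trial log of one Psi run."""

    mu_grid: np.ndarray
    sigma_grid: np.ndarray
    candidates: np.ndarray
    lapse: float
    log_posterior: np.ndarray  # flattened (n_mu * n_sigma,)
    likelihood: np.ndarray  # (n_candidates, n_mu * n_sigma), P(clockwise)
    cond_entropy: np.ndarray  # binary entropy of `likelihood`
    trial_log: list[dict] = field(default_factory=list)

    @property
    def posterior(self) -> np.ndarray:
        return np.exp(self.log_posterior - logsumexp(self.log_posterior))

    @property
    def posterior_2d(self) -> np.ndarray:
        return self.posterior.reshape(self.mu_grid.size, self.sigma_grid.size)

    def log_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trial_log)

    def to_json(self, path: str) -> None:
        payload = {
            "mu_grid": self.mu_grid.tolist(),
            "sigma_grid": self.sigma_grid.tolist(),
            "candidates": self.candidates.tolist(),
            "lapse": self.lapse,
            "log_posterior": self.log_posterior.tolist(),
            "trial_log": self.trial_log,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "PsiState":
        with open(path) as fh:
            payload = json.load(fh)
        state = psi_init(
            np.asarray(payload["mu_grid"]),
            np.asarray(payload["sigma_grid"]),
            candidates=np.asarray(payload["candidates"]),
            lapse=payload["lapse"],
        )
        state.log_posterior = np.asarray(payload["log_posterior"], dtype=float)
        state.trial_log = payload["trial_log"]
        return state


def psi_init(
    mu_grid: np.ndarray,
    sigma_grid: np.ndarray,
    candidates: np.ndarray | None = None,
    prior: np.ndarray | None = None,
    lapse: float = DEFAULT_LAPSE,
) -> PsiState:
    """Initialize a Psi run.

    ``prior`` may be any nonnegative array over the (mu, sigma) grid
    (flattened mu-major or matching 2-D shape); the default is uniform.
    ``candidates`` defaults to the mu grid.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if mu_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    if np.any(sigma_grid <= 0):
        raise ValueError("sigma grid must be positive")
    candidates = (
        mu_grid.copy() if candidates is None else np.asarray(candidates, dtype=float)
    )
    if candidates.size == 0:
        raise ValueError("candidate set must be non-empty")
    n_grid = mu_grid.size * sigma_grid.size
    if prior is None:
        prior = np.full(n_grid, 1.0 / n_grid)
    else:
        prior = np.asarray(prior, dtype=float).reshape(-1)
        if prior.size != n_grid:
            raise ValueError("prior shape does not match the parameter grid")
        if np.any(prior < 0) or prior.sum() <= 0:
            raise ValueError("prior must be nonnegative with positive mass")
        prior = prior / prior.sum()
    with np.errstate(divide="ignore"):
        log_posterior = np.log(prior)
    z = (candidates[:, None, None] - mu_grid[None, :, None]) / sigma_grid[None, None, :]
    likelihood = (lapse / 2.0 + (1.0 - lapse) * ndtr(z)).reshape(candidates.size, n_grid)
    return PsiState(
        mu_grid=mu_grid,
        sigma_grid=sigma_grid,
        candidates=candidates,
        lapse=lapse,
        log_posterior=log_posterior,
        likelihood=likelihood,
        cond_entropy=_binary_entropy(likelihood),
    )


def psi_select_stimulus(state: PsiState) -> float:
    """Candidate direction minimizing expected posterior entropy.

    Deterministic given the state; ties resolve to the lowest candidate
    index so identical seeds replay identical sessions.
    """
    q = state.posterior
    p_clock = state.likelihood @ q
    info = _binary_entropy(p_clock) - state.cond_entropy @ q
    return float(state.candidates[int(np.argmax(info))])


def expected_posterior_entropy(state: PsiState) -> np.ndarray:
    """Per-candidate expected posterior entropy (diagnostic; the
    selection rule maximizes the equivalent mutual information)."""
    q = state.posterior
    p_clock = state.likelihood @ q
    info = _binary_entropy(p_clock) - state.cond_entropy @ q
    return posterior_entropy(state) - info


def _response_is_clockwise(response) -> bool:
    if isinstance(response, str):
        if response not in (CLOCKWISE, ANTICLOCKWISE):
            raise ValueError(f"unknown response {response!r}")
        return response == CLOCKWISE
    return bool(response)


def psi_update(state: PsiState, stimulus: float, response) -> PsiState:
    """Bayes-update the posterior with one (stimulus, response) pair.

    ``stimulus`` must be a member of the candidate set.  The posterior
    is renormalized after every update; a response with zero total
    likelihood raises ``FloatingPointError``.
    """
    idx = int(np.argmin(np.abs(state.candidates - stimulus)))
    if abs(state.candidates[idx] - stimulus) > 1e-9:
        raise ValueError(f"stimulus {stimulus} is not in the candidate set")
    p = state.likelihood[idx]
    lik = p if _response_is_clockwise(response) else 1.0 - p
    with np.errstate(divide="ignore"):
        state.log_posterior = state.log_posterior + np.log(lik)
    total = logsumexp(state.log_posterior)
    if not np.isfinite(total):
        raise FloatingPointError("posterior underflow: zero total likelihood")
    state.log_posterior = state.log_posterior - total
    mu_hat, sigma_hat = _posterior_means(state)
    state.trial_log.append(
        {
            "trial": len(state.trial_log) + 1,
            "stimulus": float(stimulus),
            "response": CLOCKWISE if _response_is_clockwise(response) else ANTICLOCKWISE,
            "mu_hat": mu_hat,
            "sigma_hat": sigma_hat,
            "entropy": posterior_entropy(state),
        }
    )
    return state


def _posterior_means(state: PsiState) -> tuple[float, float]:
    q2 = state.posterior_2d
    mu_hat = float(q2.sum(axis=1) @ state.mu_grid)
    sigma_hat = float(q2.sum(axis=0) @ state.sigma_grid)
    return mu_hat, sigma_hat


def psi_estimate(state: PsiState) -> tuple[float, float]:
    """Posterior means of (mu, sigma) after at least one trial."""
    if not state.trial_log:
        raise NotReadyError("no trials have been run yet")
    return _posterior_means(state)


def posterior_entropy(state: PsiState) -> float:
    """Shannon entropy (nats) of the current posterior."""
    q = state.posterior
    nz = q > 0
    return float(-(q[nz] * np.log(q[nz])).sum())


def make_default_state(lapse: float = DEFAULT_LAPSE) -> PsiState:
    """Psi state with the package's default grids and uniform prior."""
    return psi_init(default_mu_grid(), default_sigma_grid(), lapse=lapse)
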