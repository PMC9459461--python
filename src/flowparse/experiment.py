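"""Closed-loop simulation of the induced-motion designs.

Each session couples the Psi adaptive procedure to the synthetic
flow-parsing observer: Psi proposes a physical target direction, the
full stimulus for that trial is generated (so end-to-end runs exercise
stimulus synthesis), the observer judges clockwise/anticlockwise from
the integrated global motions, and the posterior is updated.  75 trials
per session, two sessions per condition, as in the designs this package
simulates.

The four designs:

1.  field vs. ring backgrounds, background directions 0/15/30/60/90
    deg (part 2: ring outside vs. inside at a fixed 30 deg);
2.  target/background spatial frequency 3 vs. 6 c/deg crossed with
    ring position, background fixed at 30 deg;
3.  cardinal background / intercardinal target orientations vs.
    uniform-random orientations;
4.  1D (grating) vs. 2D (plaid) targets and backgrounds crossed with
    ring position.

Because the observer consumes only the integrated motions, conditions
within designs 2-4 differ by sampling noise alone — the simulation
reproduces null condition effects by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import psi as psi_mod
from .observer import ObserverParams, respond
from .stimulus import DEFAULTS, build_stimulus

__all__ = [
    "Condition",
    "SessionResult",
    "run_session",
    "run_experiment1",
    "run_experiment1_part2",
    "run_experiment2",
    "run_experiment3",
    "run_experiment4",
    "normalize_additive",
    "EXPERIMENT1_DIRECTIONS",
    "FIXED_BACKGROUND_DIRECTION",
]

EXPERIMENT1_DIRECTIONS = (0.0, 15.0, 30.0, 60.0, 90.0)
# Designs 1-part-2, 2 and 4 hold the background direction at 30 deg,
# far enough from vertical for a reliable deviation.
FIXED_BACKGROUND_DIRECTION = 30.0
N_SESSIONS_PER_CONDITION = 2


@dataclass(frozen=True)
class Condition:
    """One stimulus condition of a design, at one background direction."""

    name: str
    background_direction: float
    target_speed: float = DEFAULTS["speed"]
    background_speed: float = DEFAULTS["speed"]

    @property
    def speeds(self) -> tuple[float, float]:
        return (self.target_speed, self.background_speed)


@dataclass
class SessionResult:
    """PSE estimate and full trial log of one adaptive session."""

    condition: str
    background_direction: float
    pse: float
    sigma_hat: float
    trials: pd.DataFrame


def run_session(
    condition: Condition,
    observer: ObserverParams,
    rng: np.random.Generator,
    n_trials: int = psi_mod.DEFAULT_N_TRIALS,
    build_stimuli: bool = True,
) -> SessionResult:
    """Run one Psi session against the synthetic observer.

    With ``build_stimuli`` the per-trial stimulus is synthesized from
    the condition's named design (and its element counts logged); the
    judgment itself is mediated by the integrated global motions.
    """
    state = psi_mod.make_default_state()
    theta_b = condition.background_direction
    rows = []
    for _ in range(n_trials):
        theta_t = psi_mod.psi_select_stimulus(state)
        n_target = n_background = 0
        if build_stimuli:
            spec = build_stimulus(
                condition.name,
                background_direction=theta_b,
                target_direction=theta_t,
                rng=rng,
                target_speed=condition.target_speed,
                background_speed=condition.background_speed,
            )
            n_target = len(spec.target_elements)
            n_background = len(spec.background_elements)
        response = respond(theta_t, theta_b, condition.speeds, observer, rng)
        psi_mod.psi_update(state, theta_t, response)
        row = dict(state.trial_log[-1])
        row["theta_b"] = theta_b
        row["n_target_elements"] = n_target
        row["n_background_elements"] = n_background
        rows.append(row)
    mu_hat, sigma_hat = psi_mod.psi_estimate(state)
    return SessionResult(
        condition=condition.name,
        background_direction=theta_b,
        pse=mu_hat,
        sigma_hat=sigma_hat,
        trials=pd.DataFrame(rows),
    )


def _run_design(
    conditions: list[Condition],
    observer: ObserverParams,
    rng: np.random.Generator,
    n_sessions: int = N_SESSIONS_PER_CONDITION,
    n_trials: int = psi_mod.DEFAULT_N_TRIALS,
    build_stimuli: bool = True,
) -> pd.DataFrame:
    """Run every condition ``n_sessions`` times in random interleaved order."""
    sessions = [
        (cond, sess) for cond in conditions for sess in range(1, n_sessions + 1)
    ]
    order = rng.permutation(len(sessions))
    results = {}
    for k in order:
        cond, sess = sessions[k]
        res = run_session(cond, observer, rng, n_trials, build_stimuli)
        results[k] = {
            "condition": cond.name,
            "background_direction": cond.background_direction,
            "session": sess,
            "pse": res.pse,
            "sigma_hat": res.sigma_hat,
            "n_trials": n_trials,
        }
    return pd.DataFrame([results[k] for k in range(len(sessions))])


def run_experiment1(
    observer: ObserverParams,
    rng: np.random.Generator,
    directions=EXPERIMENT1_DIRECTIONS,
    conditions=("exp1-field", "exp1-ring"),
    **kwargs,
) -> pd.DataFrame:
    """Field vs. ring backgrounds over the five background directions.

    Returns one PSE row per condition x direction x session (2 sessions
    each by default), with field and ring sessions randomly interleaved.
    """
    conds = [
        Condition(name, float(d)) for name in conditions for d in directions
    ]
    return _run_design(conds, observer, rng, **kwargs)


def run_experiment1_part2(observer, rng, **kwargs) -> pd.DataFrame:
    """Ring outside vs. inside the target, background fixed at 30 deg."""
    conds = [
        Condition(name, FIXED_BACKGROUND_DIRECTION)
        for name in ("exp1-ring-outside", "exp1-ring-inside")
    ]
    return _run_design(conds, observer, rng, **kwargs)


def run_experiment2(observer, rng, **kwargs) -> pd.DataFrame:
    """Spatial frequency (3 vs 6 c/deg) x ring position: 8 conditions."""
    conds = [
        Condition(f"exp2-t{tsf}-b{bsf}-{pos}", FIXED_BACKGROUND_DIRECTION)
        for tsf in ("low", "high")
        for bsf in ("low", "high")
        for pos in ("outside", "inside")
    ]
    return _run_design(conds, observer, rng, **kwargs)


def run_experiment3(observer, rng, **kwargs) -> pd.DataFrame:
    """Uniform-random vs. cardinal/intercardinal orientation regimes."""
    conds = [
        Condition(name, FIXED_BACKGROUND_DIRECTION)
        for name in ("exp3-uniform", "exp3-separated")
    ]
    return _run_design(conds, observer, rng, **kwargs)


def run_experiment4(observer, rng, **kwargs) -> pd.DataFrame:
    """1D vs 2D element kinds x ring position: 8 conditions."""
    conds = [
        Condition(f"exp4-t{tk}-b{bk}-{pos}", FIXED_BACKGROUND_DIRECTION)
        for tk in ("1d", "2d")
        for bk in ("1d", "2d")
        for pos in ("outside", "inside")
    ]
    return _run_design(conds, observer, rng, **kwargs)


def normalize_additive(values, individual_baseline: float, group_mean_baseline: float):
    """Additive between-observer normalization.

    ``new = group_mean_baseline + (old - individual_baseline)``: shifts
    each observer's results so baseline-condition group means are
    unchanged while between-observer variance is removed from them.
    """
    if not (np.isfinite(individual_baseline) and np.isfinite(group_mean_baseline)):
        raise ValueError("baselines must be finite")
    return np.asarray(values, dtype=float) + (group_mean_baseline - individual_baseline)
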