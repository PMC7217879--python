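"""Kalman-filter ideal observer for the safe/risky bandit.

Rewards within a block are Gaussian around a fixed mean, so the Bayes-optimal
belief about each arm is a Gaussian posterior tracked by the Kalman filter:

    Q'(a)   = Q(a) + alpha * (r - Q(a))
    var'(a) = var(a) - alpha * var(a),      alpha = var(a) / (var(a) + tau^2(a))

with the unchosen arm untouched. Beliefs reset to the prior (mean 0,
variance tau0^2 per arm) at every block start. The per-trial regressors the
choice models consume are computed from the belief *before* the trial's
outcome:

    V  = Q(1) - Q(2)
    RU = sigma(1) - sigma(2)
    TU = sqrt(sigma^2(1) + sigma^2(2))
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import TaskConfig


@dataclass
class BeliefState:
    """Per-arm posterior mean and variance of the ideal observer."""

    Q: np.ndarray  # shape (2,), points
    var: np.ndarray  # shape (2,), points^2

    def copy(self) -> "BeliefState":
        return BeliefState(self.Q.copy(), self.var.copy())


@dataclass(frozen=True)
class Regressors:
    """Model-derived quantities available at choice time."""

    V: float
    RU: float
    TU: float
    VoverTU: float


def init_belief(config: TaskConfig) -> BeliefState:
    """Prior belief at block start: means 0, variances tau0^2."""
    return BeliefState(
        Q=np.full(2, float(config.prior_mean)),
        var=np.full(2, float(config.prior_var)),
    )


def kalman_update(
    belief: BeliefState, a_t: int, r_t: float, arm_noise_var: float
) -> tuple[BeliefState, float]:
    """One Kalman step for the chosen arm; returns the new belief and the
    learning rate alpha = var/(var + tau^2)."""
    if a_t not in (1, 2):
        raise ValueError(f"chosen arm must be 1 or 2, got {a_t!r}")
    if not math.isfinite(r_t):
        raise ValueError(f"reward must be finite, got {r_t!r}")
    if not arm_noise_var > 0:
        raise ValueError(f"arm noise variance must be positive, got {arm_noise_var!r}")
    k = a_t - 1
    new = belief.copy()
    alpha = new.var[k] / (new.var[k] + arm_noise_var)
    new.Q[k] += alpha * (r_t - new.Q[k])
    new.var[k] -= alpha * new.var[k]
    return new, float(alpha)


def compute_regressors(belief: BeliefState) -> Regressors:
    """V, RU, TU and V/TU from the current belief."""
    sigma = np.sqrt(belief.var)
    V = float(belief.Q[0] - belief.Q[1])
    RU = float(sigma[0] - sigma[1])
    TU = float(math.sqrt(belief.var[0] + belief.var[1]))
    if TU == 0.0:
        raise ValueError("total uncertainty underflowed to zero")
    return Regressors(V=V, RU=RU, TU=TU, VoverTU=V / TU)


def kalman_step_arrays(
    Q: np.ndarray,
    var: np.ndarray,
    choice_idx: np.ndarray,
    reward: np.ndarray,
    tau2: np.ndarray,
    update_mask: np.ndarray,
) -> None:
    """Vectorised in-place Kalman step across blocks.

    ``Q``/``var``/``tau2`` have shape (B, 2); ``choice_idx`` holds 0/1 arm
    indices; rows where ``update_mask`` is False (timeouts) are untouched.
    """
    rows = np.nonzero(update_mask)[0]
    c = choice_idx[rows]
    v = var[rows, c]
    alpha = v / (v + tau2[rows, c])
    Q[rows, c] += alpha * (reward[rows] - Q[rows, c])
    var[rows, c] = v - alpha * v


def run_observer(trials: pd.DataFrame, config: TaskConfig) -> pd.DataFrame:
    """Replay recorded choices through the ideal observer.

    ``trials`` must contain ``subject, run, block, trial, arm1_type,
    arm2_type, choice, reward`` with trials ordered 1..n within each block
    (the belief resets at each block start). Timeout trials (missing choice)
    yield regressors but no belief update.

    Returns a frame aligned with the input containing ``subject, run,
    block, trial, V, RU, TU, VoverTU``.
    """
    required = {"subject", "run", "block", "trial", "arm1_type", "arm2_type", "choice", "reward"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials frame is missing columns: {sorted(missing)}")

    key = trials[["subject", "run", "block"]].astype(str).agg("/".join, axis=1).to_numpy()
    boundaries = np.nonzero(np.r_[True, key[1:] != key[:-1]])[0]
    starts = boundaries
    stops = np.r_[boundaries[1:], len(trials)]
    if len(np.unique(key)) != len(starts):
        raise ValueError("trials of the same block are not contiguous")

    trial_no = trials["trial"].to_numpy(int)
    choice = trials["choice"].to_numpy(float)
    reward = trials["reward"].to_numpy(float)
    arm1 = trials["arm1_type"].to_numpy()
    arm2 = trials["arm2_type"].to_numpy()

    B = len(starts)
    Tmax = int((stops - starts).max())
    # Pad ragged blocks with inert (no-update) slots.
    pad_choice = np.zeros((B, Tmax), int)
    pad_reward = np.zeros((B, Tmax))
    pad_index = np.full((B, Tmax), -1, dtype=int)
    tau2 = np.empty((B, 2))
    for b, (lo, hi) in enumerate(zip(starts, stops)):
        tn = trial_no[lo:hi]
        if np.any(np.diff(tn) <= 0):
            raise ValueError(
                f"trial indices out of order within block starting at row {lo}"
            )
        w = hi - lo
        ch = choice[lo:hi]
        ok = np.isfinite(ch)
        pad_choice[b, :w][ok] = ch[ok].astype(int)
        pad_reward[b, :w][ok] = reward[lo:hi][ok]
        pad_index[b, :w] = np.arange(lo, hi)
        tau2[b, 0] = config.noise_var(arm1[lo])
        tau2[b, 1] = config.noise_var(arm2[lo])

    Q = np.zeros((B, 2))
    var = np.full((B, 2), float(config.prior_var))
    V = np.empty(len(trials))
    RU = np.empty(len(trials))
    TU = np.empty(len(trials))
    for t in range(Tmax):
        present = pad_index[:, t] >= 0
        idx = pad_index[present, t]
        sigma = np.sqrt(var[present])
        V[idx] = Q[present, 0] - Q[present, 1]
        RU[idx] = sigma[:, 0] - sigma[:, 1]
        TU[idx] = np.sqrt(var[present, 0] + var[present, 1])
        update = present & (pad_choice[:, t] > 0)
        kalman_step_arrays(
            Q, var, pad_choice[:, t] - 1, pad_reward[:, t], tau2, update
        )

    out = trials[["subject", "run", "block", "trial"]].copy()
    out["V"] = V
    out["RU"] = RU
    out["TU"] = TU
    out["VoverTU"] = V / TU
    return out
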