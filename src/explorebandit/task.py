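"""Generative model of the two-armed safe/risky bandit task.

Each block pairs two arms, each labelled safe (S) or risky (R). True arm
means are drawn i.i.d. from a zero-mean Gaussian prior at the start of every
block. A safe arm pays its mean exactly on every trial; a risky arm pays
Gaussian rewards around its mean. Blocks come in four conditions (RS, SR,
RR, SS) that are counterbalanced within every run: a run contains each
condition exactly once, in seeded-shuffled order.

The module also runs choice policies generatively on those bandits
(:func:`simulate_dataset`), producing trial records together with the
ideal-observer regressors that were available at choice time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONDITIONS = ("RS", "SR", "RR", "SS")

#: policies simulate_dataset understands; probit policies draw from the
#: model choice probability, explicit policies run the sampler directly.
GENERATIVE_POLICIES = (
    "softmax",
    "ucb",
    "thompson",
    "hybrid",
    "explicit-thompson",
    "explicit-ucb",
)


class ConfigError(ValueError):
    """Raised when a task configuration violates its invariants."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the bandit task generative process.

    Defaults reproduce the experiment this package models: 8 runs of 4
    counterbalanced 10-trial blocks per subject (32 blocks), arm means drawn
    from N(0, 100), risky reward variance 16 and a negligible safe
    pseudo-variance of 1e-5 points^2 (used only by the observer's Kalman
    update; emitted safe rewards equal the arm mean exactly).
    """

    n_subjects: int = 31
    n_runs_per_subject: int = 8
    n_blocks_per_run: int = 4
    n_trials_per_block: int = 10
    prior_mean: float = 0.0
    prior_var: float = 100.0
    risky_var: float = 16.0
    safe_var: float = 1e-5
    round_rewards: bool = False
    timeout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_runs_per_subject": self.n_runs_per_subject,
            "n_blocks_per_run": self.n_blocks_per_run,
            "n_trials_per_block": self.n_trials_per_block,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        for name in ("prior_var", "risky_var", "safe_var"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ConfigError(f"{name} must be a positive finite number, got {value!r}")
        if not 0.0 <= self.timeout_rate < 1.0:
            raise ConfigError(f"timeout_rate must lie in [0, 1), got {self.timeout_rate!r}")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed!r}")

    @property
    def n_blocks_per_subject(self) -> int:
        return self.n_runs_per_subject * self.n_blocks_per_run

    def noise_var(self, arm_type: str) -> float:
        """Observation noise variance tau^2 used by the Kalman filter."""
        if arm_type == "R":
            return self.risky_var
        if arm_type == "S":
            return self.safe_var
        raise ConfigError(f"unknown arm type {arm_type!r}")


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic named substream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _run_conditions(rng: np.random.Generator, n_blocks: int) -> list[str]:
    """Shuffled condition labels for one run: each condition once when
    n_blocks == 4, cyclically extended otherwise."""
    reps = -(-n_blocks // len(CONDITIONS))
    pool = np.array(CONDITIONS * reps)[:n_blocks]
    return list(pool[rng.permutation(n_blocks)])


def generate_task(config: TaskConfig) -> pd.DataFrame:
    """Draw the bandits and pre-draw both arms' rewards for every trial.

    Returns a long-format frame with one row per (subject, run, block,
    trial) and columns ``subject, run, block, condition, arm1_type,
    arm2_type, mu1, mu2, trial, reward1, reward2``. ``reward1``/``reward2``
    are the payoffs either arm *would* deliver on that trial; safe-arm
    entries equal the arm mean exactly. Deterministic given ``config.seed``;
    each subject has an independent derived stream.
    """
    T = config.n_trials_per_block
    frames = []
    for subj in range(1, config.n_subjects + 1):
        rng = _stream(config.seed, 0, subj)
        conditions: list[str] = []
        runs: list[int] = []
        for run in range(1, config.n_runs_per_subject + 1):
            conditions.extend(_run_conditions(rng, config.n_blocks_per_run))
            runs.extend([run] * config.n_blocks_per_run)
        B = config.n_blocks_per_subject
        mus = rng.normal(config.prior_mean, math.sqrt(config.prior_var), size=(B, 2))
        z = rng.standard_normal(size=(B, T, 2))
        arm_types = np.array([[c[0], c[1]] for c in conditions])
        # Safe arms pay mu exactly; the 1e-5 pseudo-variance only enters the
        # observer's update, never the emitted rewards.
        sd = np.where(arm_types == "R", math.sqrt(config.risky_var), 0.0)
        rewards = mus[:, None, :] + sd[:, None, :] * z
        if config.round_rewards:
            rewards = np.round(rewards)
        frames.append(
            pd.DataFrame(
                {
                    "subject": subj,
                    "run": np.repeat(runs, T),
                    "block": np.repeat(np.arange(1, B + 1), T),
                    "condition": np.repeat(conditions, T),
                    "arm1_type": np.repeat(arm_types[:, 0], T),
                    "arm2_type": np.repeat(arm_types[:, 1], T),
                    "mu1": np.repeat(mus[:, 0], T),
                    "mu2": np.repeat(mus[:, 1], T),
                    "trial": np.tile(np.arange(1, T + 1), B),
                    "reward1": rewards[:, :, 0].ravel(),
                    "reward2": rewards[:, :, 1].ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(
    config: TaskConfig,
    policy: str = "hybrid",
    weights=None,
    bandits: pd.DataFrame | None = None,
    ucb_bonus: float = 1.0,
) -> pd.DataFrame:
    """Run a choice policy generatively on the task.

    For every trial the running ideal-observer belief yields the regressors
    V, RU, TU and V/TU; the policy turns them (or the raw belief, for the
    explicit samplers) into a choice; the chosen arm's pre-drawn reward is
    revealed and the belief updated by the Kalman filter. Timeout trials
    (drawn i.i.d. at ``config.timeout_rate``) record no choice and trigger
    no update.

    Parameters
    ----------
    policy:
        One of :data:`GENERATIVE_POLICIES`.
    weights:
        A :class:`~explorebandit.choice_models.Weights` (or a plain sequence
        ``(w1, w2, w3)``) for the probit policies; ignored by the explicit
        samplers.
    bandits:
        Optional pre-generated frame from :func:`generate_task`, so that
        different policies can be run on the same bandits. Defaults to
        ``generate_task(config)``.

    Returns the bandit frame augmented with ``choice`` (1/2, NaN on
    timeout), ``reward`` (NaN on timeout), ``timeout`` and the pre-choice
    regressors ``V, RU, TU, VoverTU``.
    """
    from .choice_models import Weights, weight_vector

    if policy not in GENERATIVE_POLICIES:
        raise ValueError(
            f"unknown policy {policy!r}; expected one of {GENERATIVE_POLICIES}"
        )
    if bandits is None:
        bandits = generate_task(config)
    if weights is None:
        weights = Weights()
    elif not isinstance(weights, Weights):
        weights = Weights.from_sequence(weights)

    T = config.n_trials_per_block
    n = len(bandits)
    if n % T:
        raise ValueError("bandit frame length is not a multiple of n_trials_per_block")
    B = n // T

    r1 = bandits["reward1"].to_numpy(float).reshape(B, T)
    r2 = bandits["reward2"].to_numpy(float).reshape(B, T)
    arm1 = bandits["arm1_type"].to_numpy()[::T]
    arm2 = bandits["arm2_type"].to_numpy()[::T]
    tau2 = np.column_stack(
        [
            np.where(arm1 == "R", config.risky_var, config.safe_var),
            np.where(arm2 == "R", config.risky_var, config.safe_var),
        ]
    )

    # Per-subject choice streams, independent of the task stream.
    subjects = bandits["subject"].to_numpy()[::T]
    u = np.empty((B, T))
    z = np.empty((B, T, 2))
    tmo_u = np.empty((B, T))
    for subj in np.unique(subjects):
        rng = _stream(config.seed, 1, int(subj))
        mask = subjects == subj
        nb = int(mask.sum())
        u[mask] = rng.random((nb, T))
        z[mask] = rng.standard_normal((nb, T, 2))
        tmo_u[mask] = rng.random((nb, T))

    Q = np.zeros((B, 2))
    var = np.full((B, 2), float(config.prior_var))
    out_choice = np.full((B, T), np.nan)
    out_reward = np.full((B, T), np.nan)
    out_timeout = np.zeros((B, T), bool)
    out_V = np.empty((B, T))
    out_RU = np.empty((B, T))
    out_TU = np.empty((B, T))

    if policy in ("softmax", "ucb", "thompson", "hybrid"):
        wvec, cols = weight_vector(weights, policy)
    for t in range(T):
        sigma = np.sqrt(var)
        V = Q[:, 0] - Q[:, 1]
        RU = sigma[:, 0] - sigma[:, 1]
        TU = np.sqrt(var[:, 0] + var[:, 1])
        out_V[:, t], out_RU[:, t], out_TU[:, t] = V, RU, TU

        if policy == "explicit-thompson":
            qtilde = Q + sigma * z[:, t, :]
            choose1 = qtilde[:, 0] >= qtilde[:, 1]
        elif policy == "explicit-ucb":
            ucb = Q + ucb_bonus * sigma
            choose1 = ucb[:, 0] >= ucb[:, 1]
        else:
            from scipy.special import ndtr

            regs = {"V": V, "RU": RU, "VoverTU": V / TU}
            eta = np.zeros(B)
            for w, c in zip(wvec, cols):
                eta += w * regs[c]
            choose1 = u[:, t] < ndtr(eta)

        timeout = tmo_u[:, t] < config.timeout_rate
        active = ~timeout
        choice_idx = np.where(choose1, 0, 1)
        reward = np.where(choose1, r1[:, t], r2[:, t])
        out_choice[active, t] = choice_idx[active] + 1
        out_reward[active, t] = reward[active]
        out_timeout[:, t] = timeout

        rows = np.nonzero(active)[0]
        c = choice_idx[rows]
        v = var[rows, c]
        alpha = v / (v + tau2[rows, c])
        Q[rows, c] += alpha * (reward[rows] - Q[rows, c])
        var[rows, c] = v - alpha * v

    out = bandits.copy()
    out["choice"] = out_choice.ravel()
    out["reward"] = out_reward.ravel()
    out["timeout"] = out_timeout.ravel()
    out["V"] = out_V.ravel()
    out["RU"] = out_RU.ravel()
    out["TU"] = out_TU.ravel()
    out["VoverTU"] = out["V"] / out["TU"]
    return out


def with_seed(config: TaskConfig, seed: int) -> TaskConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=int(seed))
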