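"""Choice-probability models over the ideal-observer regressors.

The centrepiece is the hybrid probit

    P(a_t = 1) = Phi(w1*V + w2*RU + w3*V/TU),

which is the analytical form of a UCB/Thompson-sampling hybrid: it reduces
to pure UCB (directed exploration) when w3 = 0, to pure Thompson sampling
(random exploration) when w2 = 0, and to value-only ("softmax") choice when
w2 = w3 = 0. Augmented variants add an intercept w0 and neurally decoded
regressors (w4, w5). Explicit UCB and Thompson samplers are provided as
generative counterparts, and a per-condition intercept/slope probit captures
the qualitative behavioural signatures of the two exploration strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .observer import BeliefState

#: Regressor set per probit policy. Augmented policies additionally carry an
#: intercept (w0) when fit, mirroring how they are used for model comparison.
PROBIT_POLICIES: dict[str, tuple[str, ...]] = {
    "softmax": ("V",),
    "ucb": ("V", "RU"),
    "thompson": ("VoverTU",),
    "hybrid": ("V", "RU", "VoverTU"),
    "augmented-RU": ("V", "RU", "VoverTU", "RUhat"),
    "augmented-TU": ("V", "RU", "VoverTU", "VoverTUhat"),
    "augmented-both": ("V", "RU", "VoverTU", "RUhat", "VoverTUhat"),
    "augmented-DV": ("V", "RU", "VoverTU", "DVhat"),
}

#: Which weight slot each regressor column occupies.
_COLUMN_WEIGHT = {
    "V": "w1",
    "RU": "w2",
    "VoverTU": "w3",
    "RUhat": "w4",
    "VoverTUhat": "w4",  # w5 when RUhat is also present (augmented-both)
    "DVhat": "w4",
}

#: Probability clipping for likelihood evaluation; prevents -inf
#: log-likelihoods from the extreme V/TU values that arise on SS blocks.
PROB_EPS = 1e-10


@dataclass(frozen=True)
class Weights:
    """Choice-model coefficients. ``w0`` is the optional intercept; ``w4``
    and ``w5`` weight decoded regressors in the augmented variants."""

    w0: float | None = None
    w1: float = 0.0
    w2: float = 0.0
    w3: float = 0.0
    w4: float | None = None
    w5: float | None = None

    @classmethod
    def from_sequence(cls, seq) -> "Weights":
        """Build from a plain ``(w1, w2, w3, ...)`` sequence."""
        seq = list(seq)
        if not 1 <= len(seq) <= 3:
            raise ValueError("expected 1-3 weights (w1[, w2[, w3]])")
        seq += [0.0] * (3 - len(seq))
        return cls(w1=float(seq[0]), w2=float(seq[1]), w3=float(seq[2]))


def weight_vector(weights: Weights, policy: str) -> tuple[np.ndarray, tuple[str, ...]]:
    """Active weight values and their regressor columns for ``policy``."""
    if policy not in PROBIT_POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    cols = PROBIT_POLICIES[policy]
    values = []
    for i, c in enumerate(cols):
        slot = _COLUMN_WEIGHT[c]
        if policy == "augmented-both" and c == "VoverTUhat":
            slot = "w5"
        v = getattr(weights, slot)
        if v is None:
            raise ValueError(f"policy {policy!r} needs weight {slot} (column {c!r})")
        values.append(float(v))
    return np.asarray(values), cols


def _column(data, name: str) -> np.ndarray:
    try:
        col = data[name]
    except (KeyError, IndexError, TypeError) as exc:
        raise ValueError(f"regressor column {name!r} is missing") from exc
    return np.asarray(col, dtype=float)


def linear_predictor(weights: Weights, data, policy: str = "hybrid") -> np.ndarray:
    """w'x for the given policy; includes w0 when set on ``weights``."""
    wvec, cols = weight_vector(weights, policy)
    eta = np.zeros_like(_column(data, cols[0]))
    for w, c in zip(wvec, cols):
        eta = eta + w * _column(data, c)
    if weights.w0 is not None:
        eta = eta + weights.w0
    return eta


def choice_prob(
    weights: Weights, data, policy: str = "hybrid", eps: float = PROB_EPS
) -> np.ndarray:
    """P(choose arm 1) = Phi(linear predictor), clipped to (eps, 1-eps)."""
    p = ndtr(linear_predictor(weights, data, policy))
    return np.clip(p, eps, 1.0 - eps)


def decision_value(weights: Weights, data) -> np.ndarray:
    """DV = w1*V + w2*RU + w3*V/TU, the probit predictor of the hybrid."""
    V = _column(data, "V")
    RU = _column(data, "RU")
    try:
        VoverTU = _column(data, "VoverTU")
    except ValueError:
        VoverTU = V / _column(data, "TU")
    dv = weights.w1 * V + weights.w2 * RU + weights.w3 * VoverTU
    if not np.all(np.isfinite(dv)):
        raise ValueError("decision value is not finite")
    return dv


def explicit_thompson_choice(
    belief: BeliefState, rng: np.random.Generator
) -> tuple[int, float]:
    """Thompson sampling: draw one value per arm from its posterior and pick
    the argmax. Returns the arm (1/2) and the sampled difference
    Qtilde(1) - Qtilde(2), whose variance across draws is TU^2."""
    qtilde = belief.Q + np.sqrt(belief.var) * rng.standard_normal(2)
    diff = float(qtilde[0] - qtilde[1])
    return (1 if diff >= 0 else 2), diff


def explicit_ucb_choice(belief: BeliefState, bonus: float = 1.0) -> int:
    """Deterministic UCB: argmax_k Q(k) + bonus * sigma(k), ties to arm 1.

    The uncertainty-bonus coefficient is only defined up to proportionality;
    it defaults to 1 and is exposed as a parameter.
    """
    u = belief.Q + bonus * np.sqrt(belief.var)
    return 1 if u[0] >= u[1] else 2


def condition_model_prob(intercepts, slopes, condition, V) -> np.ndarray:
    """Per-condition probit: P(a=1) = Phi(w1^j + w2^j * V) for the trial's
    condition j, where ``intercepts``/``slopes`` map condition -> weight."""
    condition = np.asarray(condition)
    V = np.asarray(V, dtype=float)
    icpt = np.array([float(intercepts[c]) for c in condition.ravel()]).reshape(condition.shape)
    slope = np.array([float(slopes[c]) for c in condition.ravel()]).reshape(condition.shape)
    return ndtr(icpt + slope * V)
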