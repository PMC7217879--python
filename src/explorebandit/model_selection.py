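"""Random-effects Bayesian model selection across choice policies.

Per-subject log model evidence is approximated as -BIC/2 from the subject's
fixed-effects fit. Population model frequencies are then inferred with the
standard variational Dirichlet scheme (digamma-weighted responsibilities,
Dirichlet prior alpha0 = 1): exceedance probabilities give the posterior
probability that each model is the most frequent in the population, and the
protected exceedance probability (PXP) shrinks them toward uniform by the
Bayes omnibus risk (BOR), the posterior probability that model frequencies
are exactly equal:

    PXP_k = (1 - BOR) * EP_k + BOR / K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import beta as beta_dist

DEFAULT_MODELS = ("softmax", "ucb", "thompson", "hybrid")


@dataclass
class BMSResult:
    """Posterior over population model frequencies."""

    models: list[str]
    alpha: np.ndarray  # Dirichlet concentration
    expected_freq: np.ndarray
    exceedance_prob: np.ndarray
    bor: float
    pxp: np.ndarray

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "alpha": [float(a) for a in self.alpha],
            "expected_freq": [float(f) for f in self.expected_freq],
            "exceedance_prob": [float(e) for e in self.exceedance_prob],
            "bor": float(self.bor),
            "pxp": [float(p) for p in self.pxp],
        }


def evidence_from_fits(fits: dict[str, dict]) -> pd.DataFrame:
    """Per-subject approximate log evidence, -BIC/2, for each model.

    ``fits`` maps model name -> {subject -> FitResult}. Every model must
    cover the same subjects.
    """
    models = list(fits)
    subjects = sorted(fits[models[0]])
    table = {}
    for m in models:
        missing = [s for s in subjects if s not in fits[m]] + [
            s for s in fits[m] if s not in subjects
        ]
        if missing:
            raise ValueError(f"model {m!r}: subject set mismatch ({missing})")
        table[m] = [-0.5 * fits[m][s].bic for s in subjects]
    return pd.DataFrame(table, index=subjects)


def _dirichlet_vb(lme: np.ndarray, alpha0: float, max_iter: int = 10_000, tol: float = 1e-10):
    """Variational update for the random-effects model-frequency posterior."""
    n, K = lme.shape
    alpha = np.full(K, alpha0, dtype=float)
    for _ in range(max_iter):
        logu = lme + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    logu = lme + digamma(alpha) - digamma(alpha.sum())
    g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
    return alpha, g


def _free_energy(lme: np.ndarray, alpha: np.ndarray, g: np.ndarray, alpha0: float) -> float:
    """Variational free energy of the random-effects model."""
    K = len(alpha)
    asum = alpha.sum()
    dig = digamma(alpha) - digamma(asum)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.where(g > 0, g * np.log(g), 0.0).sum()
    expected = float((g * (lme + dig)).sum())
    kl = (
        gammaln(asum)
        - gammaln(alpha).sum()
        - gammaln(K * alpha0)
        + K * gammaln(alpha0)
        + float(((alpha - alpha0) * dig).sum())
    )
    return expected + entropy - kl


def exceedance_probability(
    alpha: np.ndarray, n_samples: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """P(model k has the highest population frequency) under Dir(alpha).

    Exact (Beta tail) for two models; seeded Monte-Carlo over Dirichlet
    draws otherwise.
    """
    alpha = np.asarray(alpha, dtype=float)
    K = len(alpha)
    if K == 2:
        p1 = float(beta_dist.sf(0.5, alpha[0], alpha[1]))
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    counts = np.zeros(K)
    remaining = int(n_samples)
    while remaining > 0:
        chunk = min(remaining, 200_000)
        draws = rng.standard_gamma(alpha, size=(chunk, K))
        counts += np.bincount(np.argmax(draws, axis=1), minlength=K)
        remaining -= chunk
    return counts / n_samples


def random_effects_bms(
    evidence: pd.DataFrame | np.ndarray,
    alpha0: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Random-effects BMS with protected exceedance probabilities.

    ``evidence`` holds per-subject log model evidences (subjects x models).
    The Bayes omnibus risk compares the free energy of the random-effects
    model to the null model in which every model is equally frequent:
    BOR = 1 / (1 + exp(F1 - F0)).
    """
    if isinstance(evidence, pd.DataFrame):
        models = list(evidence.columns)
        lme = evidence.to_numpy(float)
    else:
        lme = np.asarray(evidence, dtype=float)
        models = [f"model_{k}" for k in range(lme.shape[1])]
    if lme.ndim != 2 or lme.shape[0] < 2 or lme.shape[1] < 2:
        raise ValueError("evidence must be (>=2 subjects) x (>=2 models)")
    if not np.all(np.isfinite(lme)):
        raise ValueError("evidence contains non-finite values")

    n, K = lme.shape
    alpha, g = _dirichlet_vb(lme, alpha0)
    f1 = _free_energy(lme, alpha, g, alpha0)
    f0 = float(logsumexp(lme, axis=1).sum() - n * np.log(K))
    bor = float(1.0 / (1.0 + np.exp(np.clip(f1 - f0, -700, 700))))
    ep = exceedance_probability(alpha, n_samples=n_samples, seed=seed)
    pxp = (1.0 - bor) * ep + bor / K
    return BMSResult(
        models=models,
        alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        exceedance_prob=ep,
        bor=bor,
        pxp=pxp,
    )


def compare_models(
    data: pd.DataFrame,
    models: tuple[str, ...] = DEFAULT_MODELS,
    include_intercept: bool = False,
    seed: int = 0,
    n_samples: int = 1_000_000,
):
    """Fit each lesioned policy per subject, tabulate information criteria
    and run random-effects BMS on the -BIC/2 evidences.

    Returns ``(table, bms, evidence)`` where ``table`` sums LL/AIC/BIC/
    deviance across subjects per model.
    """
    from .fit import fit_probit_per_subject

    fits = {m: fit_probit_per_subject(data, m, include_intercept) for m in models}
    rows = []
    for m in models:
        per = fits[m].values()
        failed = [s for s, r in fits[m].items() if not r.converged]
        rows.append(
            {
                "model": m,
                "n_params": sum(r.n_params for r in per),
                "loglik": sum(r.loglik for r in per),
                "aic": sum(r.aic for r in per),
                "bic": sum(r.bic for r in per),
                "deviance": sum(r.deviance for r in per),
                "n_obs": sum(r.n_obs for r in per),
                "n_not_converged": len(failed),
            }
        )
    table = pd.DataFrame(rows).set_index("model")
    evidence = evidence_from_fits(fits)
    bms = random_effects_bms(evidence, seed=seed, n_samples=n_samples)
    return table, bms, evidence
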