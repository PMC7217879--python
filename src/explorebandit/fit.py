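"""Maximum-likelihood fitting of the probit choice models.

Per-subject (fixed-effects) fits use a damped Newton optimiser on the
Bernoulli-probit log-likelihood with analytic gradient and Hessian; the
Hessian is positive definite for the probit, so Newton steps with an Armijo
backtracking line search converge reliably. Regressor columns are rescaled
to unit root-mean-square internally (the MLE is equivariant under column
rescaling), which keeps the problem well conditioned despite the huge V/TU
values that arise on safe/safe blocks. Two starts (the origin and a small
deterministic perturbation) guard against the unlikely event of a poor
line-search path.

Group-level fits use a Laplace approximation to the marginal likelihood of
a mixed-effects probit with per-coefficient (diagonal) random-effect
variances: inner Newton iterations find each subject's posterior mode,
and an outer quasi-Newton optimiser moves the fixed effects and
log-variances.

The module also provides the per-condition intercept/slope model, the
generated-vs-recovered parameter-recovery experiment, and generative
performance metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr
from scipy.stats import norm, pearsonr

from .choice_models import PROBIT_POLICIES, Weights
from .task import CONDITIONS, TaskConfig, simulate_dataset

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: Hard cap on standardised weights; reached only under complete
#: separation, where the probit NLL has no interior minimum.
WEIGHT_CAP = 1e8

#: Standardised weights beyond this are flagged as separation.
SEPARATION_THRESHOLD = 1e6

#: Convergence tolerance: max |gradient| per observation.
GRAD_TOL = 1e-8


@dataclass
class FitResult:
    """A fitted probit choice model.

    ``weights`` etc. are aligned with ``columns`` (intercept first when
    present). The information criteria are the usual identities:
    AIC = 2k - 2*LL, BIC = k*ln(n) - 2*LL, deviance = -2*LL.
    """

    model: str
    columns: list[str]
    weights: np.ndarray
    se: np.ndarray
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    warnings: list[str] = field(default_factory=list)
    cov: np.ndarray | None = None
    per_subject_effects: pd.DataFrame | None = None
    random_effect_vars: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * math.log(self.n_obs) - 2.0 * self.loglik

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.weights / self.se

    @property
    def pvalues(self) -> np.ndarray:
        """Wald p-values (estimate/SE against the standard normal)."""
        return 2.0 * norm.sf(np.abs(self.zvalues))

    def coef(self, name: str) -> float:
        return float(self.weights[self.columns.index(name)])

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "columns": list(self.columns),
            "weights": [float(w) for w in self.weights],
            "se": [float(s) for s in self.se],
            "pvalues": [float(p) for p in self.pvalues],
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "n_params": int(self.n_params),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "deviance": float(self.deviance),
            "converged": bool(self.converged),
            "warnings": list(self.warnings),
        }
        if self.random_effect_vars is not None:
            d["random_effect_vars"] = [float(v) for v in self.random_effect_vars]
        return d


# ---------------------------------------------------------------------------
# Probit likelihood primitives (s = +1 for "chose arm 1", -1 otherwise)
# ---------------------------------------------------------------------------

def _nll(w: np.ndarray, X: np.ndarray, s: np.ndarray) -> float:
    return -float(log_ndtr(s * (X @ w)).sum())


def _nll_grad_hess(w: np.ndarray, X: np.ndarray, s: np.ndarray):
    z = s * (X @ w)
    logcdf = log_ndtr(z)
    # inverse Mills ratio phi(z)/Phi(z), numerically stable in both tails
    r = np.exp(-0.5 * z * z - _LOG_SQRT_2PI - logcdf)
    nll = -float(logcdf.sum())
    grad = -(X.T @ (s * r))
    lam = r * (r + z)  # > 0: the probit NLL is convex
    hess = X.T @ (X * lam[:, None])
    return nll, grad, hess


def _newton_probit(
    X: np.ndarray,
    s: np.ndarray,
    start: np.ndarray,
    gtol: float = GRAD_TOL,
    max_iter: int = 100,
    cap: float = WEIGHT_CAP,
):
    """Damped Newton on the probit NLL. Returns (w, nll, converged, capped)."""
    n, p = X.shape
    w = start.astype(float).copy()
    nll, grad, hess = _nll_grad_hess(w, X, s)
    converged = False
    capped = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) <= gtol * n:
            converged = True
            break
        ridge = 1e-12 * (np.trace(hess) / p + 1.0)
        try:
            step = np.linalg.solve(hess + ridge * np.eye(p), -grad)
        except np.linalg.LinAlgError:
            step = -grad / (np.abs(np.diag(hess)) + 1.0)
        slope = float(grad @ step)
        t = 1.0
        for _ls in range(60):
            w_new = np.clip(w + t * step, -cap, cap)
            nll_new = _nll(w_new, X, s)
            if nll_new <= nll + 1e-4 * t * slope or nll_new < nll:
                break
            t *= 0.5
        else:
            converged = np.max(np.abs(grad)) <= 1e3 * gtol * n
            break
        if np.max(np.abs(w_new - w)) < 1e-14 * (1.0 + np.max(np.abs(w))):
            w, nll = w_new, nll_new
            converged = True
            break
        w, nll = w_new, nll_new
        nll, grad, hess = _nll_grad_hess(w, X, s)
    # Complete separation: every observation is predicted with a strictly
    # positive margin, so the likelihood has no interior maximum and the
    # converged point is only where the gradient underflowed.
    margin = s * (X @ w)
    if np.any(np.abs(w) >= SEPARATION_THRESHOLD) or (
        len(margin) > 0 and margin.min() > 0 and nll < 1e-3 * len(s)
    ):
        capped = True
    return w, nll, converged, capped


def fit_probit_design(
    X: np.ndarray,
    y1: np.ndarray,
    columns: list[str],
    model: str = "probit",
) -> FitResult:
    """Fit a probit by ML on an explicit design matrix.

    ``y1`` is boolean (True = chose arm 1). Columns are standardised
    internally; estimates, SEs and the covariance are returned on the
    original scale. Complete separation is flagged and the offending
    weights are capped rather than allowed to diverge.
    """
    X = np.asarray(X, dtype=float)
    y1 = np.asarray(y1, dtype=bool)
    if X.ndim != 2 or X.shape[0] != y1.shape[0]:
        raise ValueError("design/response shape mismatch")
    n, p = X.shape
    if n < 1:
        raise ValueError("no usable trials")
    s = np.where(y1, 1.0, -1.0)
    scale = np.sqrt(np.mean(X * X, axis=0))
    dead = scale == 0
    scale[dead] = 1.0
    Xs = X / scale

    warnings: list[str] = []
    if np.any(dead):
        warnings.append(
            "all-zero design columns: " + ", ".join(np.array(columns)[dead])
        )

    starts = [np.zeros(p), np.full(p, 0.05) * (-1.0) ** np.arange(p)]
    best = None
    for w0 in starts:
        sol = _newton_probit(Xs, s, w0)
        if best is None or sol[1] < best[1]:
            best = sol
    w_s, nll, converged, capped = best
    if capped:
        warnings.append("possible complete separation; weights capped")
    _, _, hess = _nll_grad_hess(w_s, Xs, s)
    try:
        cov_s = np.linalg.inv(hess)
        se_s = np.sqrt(np.clip(np.diag(cov_s), 0.0, None))
    except np.linalg.LinAlgError:
        cov_s = np.full((p, p), np.nan)
        se_s = np.full(p, np.nan)
        warnings.append("singular Hessian at the optimum")
    w = w_s / scale
    se = se_s / scale
    cov = cov_s / np.outer(scale, scale)
    w[dead] = np.nan
    se[dead] = np.nan
    return FitResult(
        model=model,
        columns=list(columns),
        weights=w,
        se=se,
        loglik=-nll,
        n_obs=n,
        n_params=int(p - dead.sum()),
        converged=bool(converged),
        warnings=warnings,
        cov=cov,
    )


# ---------------------------------------------------------------------------
# Policy-level interfaces
# ---------------------------------------------------------------------------

def _usable(data: pd.DataFrame) -> pd.DataFrame:
    """Drop timeout trials; require a recorded choice."""
    if "timeout" in data.columns:
        data = data.loc[~data["timeout"].astype(bool)]
    data = data.loc[np.isfinite(data["choice"].to_numpy(float))]
    if len(data) == 0:
        raise ValueError("no usable (non-timeout) trials")
    return data


def _policy_design(data: pd.DataFrame, policy: str, include_intercept: bool):
    if policy not in PROBIT_POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    cols = list(PROBIT_POLICIES[policy])
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing regressor columns: {missing}")
    X = data[cols].to_numpy(float)
    names = cols
    if include_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + cols
    return X, names


def fit_probit_ml(
    data: pd.DataFrame, policy: str = "hybrid", include_intercept: bool = False
) -> FitResult:
    """Fixed-effects ML fit of a probit policy on (pooled) trial data.

    ``data`` must carry ``choice`` (1/2; NaN on timeout) and the policy's
    regressor columns. Timeout trials are excluded.
    """
    data = _usable(data)
    X, names = _policy_design(data, policy, include_intercept)
    y1 = data["choice"].to_numpy(float) == 1.0
    return fit_probit_design(X, y1, names, model=policy)


def fit_probit_per_subject(
    data: pd.DataFrame, policy: str = "hybrid", include_intercept: bool = False
) -> dict[int, FitResult]:
    """Independent fixed-effects fit for every subject."""
    out: dict[int, FitResult] = {}
    for subj, grp in data.groupby("subject", sort=True):
        out[subj] = fit_probit_ml(grp, policy, include_intercept)
    return out


# ---------------------------------------------------------------------------
# Hierarchical (Laplace) mixed-effects probit
# ---------------------------------------------------------------------------

def _laplace_subject(Xs, s, beta, inv_s2, log_s2, b_start, gtol=1e-10):
    """Laplace log marginal likelihood contribution for one subject.

    Finds the mode of l(beta + b) - 0.5 b' D^-1 b by Newton iterations and
    returns (log-lik contribution, mode b).
    """
    p = len(beta)
    b = b_start.copy()
    for _ in range(100):
        nll, grad, hess = _nll_grad_hess(beta + b, Xs, s)
        g = -grad - inv_s2 * b  # gradient of the objective being maximised
        H = hess + np.diag(inv_s2)
        step = np.linalg.solve(H, g)
        t = 1.0
        obj = -nll - 0.5 * float(b @ (inv_s2 * b))
        for _ls in range(50):
            b_new = b + t * step
            obj_new = -_nll(beta + b_new, Xs, s) - 0.5 * float(
                b_new @ (inv_s2 * b_new)
            )
            if obj_new >= obj:
                break
            t *= 0.5
        b = b_new
        if np.max(np.abs(g)) < gtol * (1.0 + len(s)) or np.max(np.abs(t * step)) < 1e-12:
            break
    nll, _, hess = _nll_grad_hess(beta + b, Xs, s)
    H = hess + np.diag(inv_s2)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf, b
    ll = (
        -nll
        - 0.5 * float(b @ (inv_s2 * b))
        - 0.5 * float(np.sum(log_s2))
        - 0.5 * logdet
    )
    return ll, b


def fit_probit_hierarchical(
    data: pd.DataFrame,
    policy: str = "hybrid",
    include_intercept: bool = False,
    max_outer: int = 300,
) -> FitResult:
    """Mixed-effects probit with diagonal random-effect covariance.

    Model: choice_it ~ Bernoulli(Phi(x_it'(beta + b_i))) with
    b_i ~ N(0, diag(s^2)). The marginal likelihood is approximated by
    Laplace's method around each subject's posterior mode, and the fixed
    effects beta and log-variances are maximised jointly by L-BFGS-B.
    Returns the fixed effects with the per-subject conditional modes in
    ``per_subject_effects`` and the variance estimates in
    ``random_effect_vars``. With a single subject this reduces to
    :func:`fit_probit_ml`.
    """
    data = _usable(data)
    subjects = sorted(data["subject"].unique())
    if len(subjects) == 1:
        res = fit_probit_ml(data, policy, include_intercept)
        res.per_subject_effects = pd.DataFrame(
            [res.weights], index=subjects, columns=res.columns
        )
        return res

    X_all, names = _policy_design(data, policy, include_intercept)
    p = X_all.shape[1]
    scale = np.sqrt(np.mean(X_all * X_all, axis=0))
    scale[scale == 0] = 1.0
    subj_arr = data["subject"].to_numpy()
    y1 = data["choice"].to_numpy(float) == 1.0
    s_all = np.where(y1, 1.0, -1.0)
    per_subj = []
    for subj in subjects:
        m = subj_arr == subj
        per_subj.append((X_all[m] / scale, s_all[m]))

    pooled = fit_probit_design(X_all / scale, y1, names, model=policy)
    theta0 = np.r_[pooled.weights, np.full(p, math.log(0.25))]
    modes = {i: np.zeros(p) for i in range(len(subjects))}

    def negloglik(theta: np.ndarray) -> float:
        beta = theta[:p]
        log_s2 = np.clip(theta[p:], -25.0, 10.0)
        inv_s2 = np.exp(-log_s2)
        total = 0.0
        for i, (Xs, s) in enumerate(per_subj):
            ll, b = _laplace_subject(Xs, s, beta, inv_s2, log_s2, modes[i])
            modes[i] = b
            if not np.isfinite(ll):
                return 1e12
            total += ll
        return -total

    bounds = [(None, None)] * p + [(-25.0, 10.0)] * p
    sol = optimize.minimize(
        negloglik,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_outer, "ftol": 1e-12, "gtol": 1e-7},
    )
    beta_s = sol.x[:p]
    log_s2 = np.clip(sol.x[p:], -25.0, 10.0)
    inv_s2 = np.exp(-log_s2)
    loglik = -float(sol.fun)

    # Fixed-effect SEs from a central-difference Hessian over beta only.
    h = 1e-4 * (1.0 + np.abs(beta_s))
    H = np.empty((p, p))
    def f_beta(b):
        return negloglik(np.r_[b, log_s2])
    f0 = f_beta(beta_s)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                H[i, i] = (f_beta(beta_s + ei) - 2 * f0 + f_beta(beta_s - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f_beta(beta_s + ei + ej)
                    - f_beta(beta_s + ei - ej)
                    - f_beta(beta_s - ei + ej)
                    + f_beta(beta_s - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov_s = np.linalg.inv(H)
        se_s = np.sqrt(np.clip(np.diag(cov_s), 0.0, None))
    except np.linalg.LinAlgError:
        cov_s = None
        se_s = np.full(p, np.nan)

    # Final per-subject conditional modes at the optimum.
    effects = np.empty((len(subjects), p))
    for i, (Xs, s) in enumerate(per_subj):
        _, b = _laplace_subject(Xs, s, beta_s, inv_s2, log_s2, modes[i])
        effects[i] = (beta_s + b) / scale

    return FitResult(
        model=policy,
        columns=list(names),
        weights=beta_s / scale,
        se=se_s / scale,
        loglik=loglik,
        n_obs=len(data),
        n_params=2 * p,
        converged=bool(sol.success),
        warnings=[] if sol.success else [f"outer optimiser: {sol.message}"],
        cov=None if cov_s is None else cov_s / np.outer(scale, scale),
        per_subject_effects=pd.DataFrame(effects, index=subjects, columns=names),
        random_effect_vars=np.exp(log_s2) / scale**2,
    )


# ---------------------------------------------------------------------------
# Condition intercept/slope model
# ---------------------------------------------------------------------------

@dataclass
class ConditionFit:
    """Per-condition intercepts and slopes of the choice function."""

    per_subject: pd.DataFrame  # one row per subject, columns icpt_*/slope_*
    summary: pd.DataFrame  # per condition: intercept, intercept_se, slope, slope_se
    missing_conditions: dict[int, list[str]]


def _condition_design(data: pd.DataFrame):
    V = data["V"].to_numpy(float)
    cond = data["condition"].to_numpy()
    cols, names = [], []
    for j in CONDITIONS:
        pi = (cond == j).astype(float)
        cols += [pi, pi * V]
        names += [f"icpt_{j}", f"slope_{j}"]
    return np.column_stack(cols), names


def fit_condition_model(data: pd.DataFrame, hierarchical: bool = False) -> ConditionFit:
    """Fit P(a=1) = Phi(sum_j w1^j pi_j + w2^j pi_j V) per subject.

    The summary reports the cross-subject mean and standard error of each
    condition's intercept and slope. Conditions absent from a subject's data
    yield NaN estimates for that subject and are flagged.

    With ``hierarchical=True`` a single Laplace mixed-effects fit is run on
    the 8-column condition design instead of per-subject ML, and the
    summary reports its per-subject conditional modes.
    """
    data = _usable(data)
    if hierarchical:
        aug = data.copy()
        X, names = _condition_design(aug)
        for c, name in enumerate(names):
            aug[name] = X[:, c]
        policy_cols = tuple(names)
        saved = PROBIT_POLICIES.get("_condition")
        PROBIT_POLICIES["_condition"] = policy_cols
        try:
            from .choice_models import _COLUMN_WEIGHT  # noqa: F401
            res = _fit_condition_hierarchical(aug, names)
        finally:
            if saved is None:
                PROBIT_POLICIES.pop("_condition", None)
            else:
                PROBIT_POLICIES["_condition"] = saved
        return res

    rows = {}
    missing: dict[int, list[str]] = {}
    for subj, grp in data.groupby("subject", sort=True):
        X, names = _condition_design(grp)
        present = np.sqrt(np.mean(X * X, axis=0)) > 0
        res = fit_probit_design(
            X[:, present], grp["choice"].to_numpy(float) == 1.0,
            [n for n, m in zip(names, present) if m], model="condition",
        )
        row = dict.fromkeys(names, np.nan)
        for name, w in zip(res.columns, res.weights):
            row[name] = w
        rows[subj] = row
        absent = sorted({n.split("_")[1] for n, m in zip(names, present) if not m})
        if absent:
            missing[subj] = absent
    per_subject = pd.DataFrame.from_dict(rows, orient="index")
    summary = _condition_summary(per_subject)
    return ConditionFit(per_subject=per_subject, summary=summary, missing_conditions=missing)


def _condition_summary(per_subject: pd.DataFrame) -> pd.DataFrame:
    rows = []
    n = len(per_subject)
    for j in CONDITIONS:
        icpt = per_subject[f"icpt_{j}"].to_numpy(float)
        slope = per_subject[f"slope_{j}"].to_numpy(float)
        rows.append(
            {
                "condition": j,
                "intercept": np.nanmean(icpt),
                "intercept_se": np.nanstd(icpt, ddof=1) / math.sqrt(max(np.isfinite(icpt).sum(), 1)),
                "slope": np.nanmean(slope),
                "slope_se": np.nanstd(slope, ddof=1) / math.sqrt(max(np.isfinite(slope).sum(), 1)),
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def _fit_condition_hierarchical(aug: pd.DataFrame, names: list[str]) -> ConditionFit:
    res = fit_probit_hierarchical(aug, policy="_condition")
    per_subject = res.per_subject_effects
    summary = _condition_summary(per_subject)
    return ConditionFit(per_subject=per_subject, summary=summary, missing_conditions={})


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    """Generated-vs-recovered weights across generative simulations."""

    generated: np.ndarray  # (n_sims, 3)
    recovered: np.ndarray  # (n_sims, 3)
    per_coef_r: np.ndarray  # (3,)
    pairwise_r: np.ndarray  # (3, 3) among recovered coefficients
    n_failed: int
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for i, name in enumerate(("w1", "w2", "w3")):
            cols[f"generated_{name}"] = self.generated[:, i]
            cols[f"recovered_{name}"] = self.recovered[:, i]
        return pd.DataFrame(cols)


def parameter_recovery(
    n_sims: int,
    config: TaskConfig | None = None,
    weight_prior_sd: float = math.sqrt(10.0),
    seed: int = 0,
    hierarchical: bool = False,
) -> RecoveryResult:
    """Simulate-and-refit validation of the hybrid-model fitting pipeline.

    Each simulation draws one weight vector w ~ N(0, weight_prior_sd^2 I),
    simulates the full experiment (fresh bandits, default 31 subjects of
    32 x 10 trials) with the hybrid policy, and refits the weights — by a
    pooled fixed-effects probit across the simulated subjects by default,
    or by the (much slower) hierarchical fit when requested. Reports the
    per-coefficient Pearson correlation between generated and recovered
    weights and the pairwise correlations among the recovered weights.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if config is None:
        config = TaskConfig()
    generated, recovered, notes = [], [], []
    n_failed = 0
    for i in range(n_sims):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7, i]))
        w_true = rng.normal(0.0, weight_prior_sd, 3)
        sim_seed = int(rng.integers(2**31))
        data = simulate_dataset(
            replace(config, seed=sim_seed), "hybrid", Weights.from_sequence(w_true)
        )
        try:
            if hierarchical:
                res = fit_probit_hierarchical(data, "hybrid")
            else:
                res = fit_probit_ml(data, "hybrid")
            if not res.converged:
                raise RuntimeError("fit did not converge")
        except Exception as exc:  # noqa: BLE001 - failures are data, not bugs
            n_failed += 1
            notes.append(f"simulation {i}: {exc}")
            continue
        generated.append(w_true)
        recovered.append(res.weights[-3:])
    generated = np.asarray(generated).reshape(-1, 3)
    recovered = np.asarray(recovered).reshape(-1, 3)

    per_coef = np.full(3, np.nan)
    for k in range(3):
        if len(generated) >= 2 and np.std(generated[:, k]) > 0 and np.std(recovered[:, k]) > 0:
            per_coef[k] = pearsonr(generated[:, k], recovered[:, k]).statistic
        else:
            notes.append(f"coefficient w{k + 1}: correlation undefined (degenerate)")
    pairwise = np.full((3, 3), np.nan)
    if len(recovered) >= 2:
        sd = recovered.std(axis=0)
        if np.all(sd > 0):
            pairwise = np.corrcoef(recovered, rowvar=False)
    return RecoveryResult(
        generated=generated,
        recovered=recovered,
        per_coef_r=per_coef,
        pairwise_r=pairwise,
        n_failed=n_failed,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Generative performance
# ---------------------------------------------------------------------------

def performance(trials: pd.DataFrame, min_trial: int = 1) -> float:
    """Proportion of non-timeout trials (from ``min_trial`` onward) on which
    the chosen arm had the larger true mean. Blocks with exactly tied means
    (measure zero) are excluded."""
    t = trials.loc[trials["trial"] >= min_trial]
    choice = t["choice"].to_numpy(float)
    ok = np.isfinite(choice)
    mu1 = t["mu1"].to_numpy(float)
    mu2 = t["mu2"].to_numpy(float)
    ok &= mu1 != mu2
    if not ok.any():
        raise ValueError("no scorable trials")
    better = np.where(mu1 > mu2, 1.0, 2.0)
    return float(np.mean(choice[ok] == better[ok]))


def performance_by_trial(trials: pd.DataFrame) -> pd.Series:
    """Learning curve: performance as a function of within-block trial index."""
    t = trials.copy()
    choice = t["choice"].to_numpy(float)
    better = np.where(t["mu1"].to_numpy(float) > t["mu2"].to_numpy(float), 1.0, 2.0)
    t["correct"] = np.where(np.isfinite(choice), choice == better, np.nan)
    t = t.loc[t["mu1"] != t["mu2"]]
    return t.groupby("trial")["correct"].mean()


def grid_performance(
    config: TaskConfig,
    grid_points: int = 16,
    iterations: int = 10,
    w_max: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generative performance over an evenly spaced (w1, w2, w3) grid.

    Every grid point is simulated ``iterations`` times on fresh bandits and
    the better-option proportion is averaged across simulated subjects and
    iterations. The full 16-point grid is expensive; smaller grids scale
    the same surface down.
    """
    if grid_points < 2:
        raise ValueError("grid must have at least 2 points per coefficient")
    values = np.linspace(0.0, w_max, grid_points)
    rows = []
    cell = 0
    for w1 in values:
        for w2 in values:
            for w3 in values:
                perf = 0.0
                for it in range(iterations):
                    rng = np.random.default_rng(
                        np.random.SeedSequence([int(seed), 11, cell, it])
                    )
                    sim_seed = int(rng.integers(2**31))
                    data = simulate_dataset(
                        replace(config, seed=sim_seed),
                        "hybrid",
                        Weights(w1=w1, w2=w2, w3=w3),
                    )
                    perf += performance(data)
                rows.append({"w1": w1, "w2": w2, "w3": w3, "performance": perf / iterations})
                cell += 1
    return pd.DataFrame(rows)
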