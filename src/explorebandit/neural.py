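"""Synthetic neural signals and GLM-inversion (ridge) decoding.

A region's trial-level signal is modelled as a linear combination of named
design columns (|RU|, TU, |V|, |V|/TU, |DV|, plus arbitrary nuisance
columns) with known per-voxel coefficients beta and additive Gaussian
noise. This is a trial-indexed abstraction of an ROI's event-related
response: the haemodynamic machinery is out of scope, and the decoding
arithmetic below is identical with or without it.

Decoding inverts the GLM one regressor at a time with a ridge penalty:

    est_t = (y_t - sum_{i != target} X_{t,i} beta_i) * beta_target
            / (beta_target^2 + lambda)

per voxel, then averages across the region's voxels. Unsigned estimates of
|RU| and |DV| get their sign from the model-based series; decoded TU is
floored at a small epsilon before forming V/TU-hat.

The module also fits the augmented choice models (baseline-with-intercept
vs. baseline + decoded regressor) and runs the residual-variance test: under
a sampling (Thompson) implementation of the decision value, the variance of
the signal around its mean scales with TU^2, so squared GLM residuals should
correlate positively with TU^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .choice_models import Weights, decision_value

#: floor applied to decoded TU before it divides V (the decode can dip
#: arbitrarily close to zero; the choice of floor is an implementation
#: convention, not part of the decoding model)
TU_FLOOR = 1e-6

STANDARD_COLUMNS = ("absRU", "TU", "absV", "absVoverTU", "absDV")


@dataclass
class NeuralPanel:
    """Per-trial, per-voxel synthetic region signal with its generating GLM."""

    y: np.ndarray  # (n_trials, n_voxels)
    X: pd.DataFrame  # (n_trials, n_columns) design
    beta: np.ndarray  # (n_voxels, n_columns)
    lam: float  # ridge constant lambda >= 0
    noise_sd: float
    mode: str = "closed-form-DV"

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_voxels(self) -> int:
        return self.y.shape[1]


@dataclass
class DecodedEstimates:
    """Signed decoded relative uncertainty, floored decoded total
    uncertainty and signed decoded decision value, per trial."""

    ru_hat: np.ndarray | None = None
    tu_hat: np.ndarray | None = None
    dv_hat: np.ndarray | None = None


def build_design(
    regs: pd.DataFrame,
    weights: Weights | None = None,
    columns: tuple[str, ...] = STANDARD_COLUMNS,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the named design columns from the observer regressors.

    ``absDV`` requires ``weights`` (it is the absolute value of the hybrid
    predictor). ``extra`` appends nuisance columns verbatim.
    """
    out = {}
    for c in columns:
        if c == "absRU":
            out[c] = np.abs(regs["RU"].to_numpy(float))
        elif c == "TU":
            out[c] = regs["TU"].to_numpy(float)
        elif c == "absV":
            out[c] = np.abs(regs["V"].to_numpy(float))
        elif c == "absVoverTU":
            out[c] = np.abs(regs["VoverTU"].to_numpy(float))
        elif c == "absDV":
            if weights is None:
                raise ValueError("absDV design column requires model weights")
            out[c] = np.abs(decision_value(weights, regs))
        else:
            raise ValueError(f"unknown design column {c!r}")
    X = pd.DataFrame(out, index=regs.index)
    if extra is not None:
        dup = set(X.columns) & set(extra.columns)
        if dup:
            raise ValueError(f"duplicate design columns: {sorted(dup)}")
        X = pd.concat([X, extra.set_index(regs.index)], axis=1)
    return X


def generate_neural(
    regs: pd.DataFrame,
    encoding: dict[str, float],
    n_voxels: int = 1,
    noise_sd: float = 1.0,
    lam: float = 1.0,
    mode: str = "closed-form-DV",
    weights: Weights | None = None,
    extra: pd.DataFrame | None = None,
    seed: int = 0,
) -> NeuralPanel:
    """Simulate a region that linearly encodes the given design columns.

    ``encoding`` maps column name -> beta (shared across voxels). In
    ``"thompson-sample-DV"`` mode the decision-value contribution carries
    per-trial sampling noise: the sampled value difference Qtilde(1) -
    Qtilde(2) is distributed N(V, TU^2), so substituting it for V in the
    decision value adds w3 * (Qtilde-diff - V) ~ N(0, w3^2 TU^2) on top of
    the mean |DV| signal, shared across the region's voxels. Residual
    variance around the mean DV signal therefore scales with TU^2 by
    construction.
    """
    if mode not in ("closed-form-DV", "thompson-sample-DV"):
        raise ValueError(f"unknown mode {mode!r}")
    std_cols = tuple(c for c in encoding if c in STANDARD_COLUMNS)
    unknown = [
        c
        for c in encoding
        if c not in STANDARD_COLUMNS and (extra is None or c not in extra.columns)
    ]
    if unknown:
        raise ValueError(f"unknown design columns in encoding: {unknown}")
    X = build_design(regs, weights=weights, columns=std_cols, extra=extra)
    n = len(X)
    beta = np.zeros((n_voxels, X.shape[1]))
    for j, c in enumerate(X.columns):
        beta[:, j] = encoding.get(c, 0.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    y = X.to_numpy(float) @ beta.T + rng.normal(0.0, noise_sd, size=(n, n_voxels))
    if mode == "thompson-sample-DV":
        if "absDV" not in encoding or weights is None:
            raise ValueError("thompson-sample-DV mode needs an absDV encoding and weights")
        tu = regs["TU"].to_numpy(float)
        sample_noise = weights.w3 * tu * rng.standard_normal(n)
        y = y + np.outer(sample_noise, beta[:, list(X.columns).index("absDV")])
    return NeuralPanel(y=y, X=X, beta=beta, lam=float(lam), noise_sd=float(noise_sd), mode=mode)


def decode_modulator(
    panel: NeuralPanel, target: str, return_voxels: bool = False
) -> np.ndarray:
    """Ridge-inversion decode of one design column, averaged over voxels."""
    if panel.lam < 0:
        raise ValueError("ridge constant lambda must be >= 0")
    cols = panel.columns
    if target not in cols:
        raise ValueError(f"target column {target!r} not in design {cols}")
    j = cols.index(target)
    beta_t = panel.beta[:, j]
    if panel.lam == 0 and np.any(beta_t == 0):
        raise ValueError("beta_target = 0 with lambda = 0: decode undefined")
    Xother = panel.X.to_numpy(float).copy()
    Xother[:, j] = 0.0
    residual = panel.y - Xother @ panel.beta.T  # (n, v)
    est = residual * beta_t / (beta_t**2 + panel.lam)
    if return_voxels:
        return est
    return est.mean(axis=1)


def sign_adjust(unsigned: np.ndarray, model_signed: np.ndarray) -> np.ndarray:
    """Give an unsigned decode the sign of its model-based counterpart:
    +|est| where the model value is >= 0, -|est| where it is negative."""
    unsigned = np.asarray(unsigned, dtype=float)
    model_signed = np.asarray(model_signed, dtype=float)
    if unsigned.shape != model_signed.shape:
        raise ValueError("length mismatch between decode and model series")
    return np.where(model_signed >= 0, np.abs(unsigned), -np.abs(unsigned))


def decode_estimates(
    panel: NeuralPanel,
    regs: pd.DataFrame,
    weights: Weights | None = None,
    tu_floor: float = TU_FLOOR,
) -> DecodedEstimates:
    """Decode whichever of |RU|, TU and |DV| the panel's design contains."""
    out = DecodedEstimates()
    if "absRU" in panel.columns:
        out.ru_hat = sign_adjust(
            decode_modulator(panel, "absRU"), regs["RU"].to_numpy(float)
        )
    if "TU" in panel.columns:
        out.tu_hat = np.maximum(decode_modulator(panel, "TU"), tu_floor)
    if "absDV" in panel.columns:
        if weights is None:
            raise ValueError("decoding DV requires model weights")
        out.dv_hat = sign_adjust(
            decode_modulator(panel, "absDV"), decision_value(weights, regs)
        )
    return out


# ---------------------------------------------------------------------------
# Augmented choice models
# ---------------------------------------------------------------------------

_VARIANT_POLICY = {
    "RU": "augmented-RU",
    "TU": "augmented-TU",
    "both": "augmented-both",
    "DV": "augmented-DV",
}


@dataclass
class AugmentedComparison:
    """Baseline-with-intercept vs. decoded-regressor-augmented fit."""

    variant: str
    baseline: "FitResult"  # noqa: F821 - forward ref to fit.FitResult
    augmented: "FitResult"  # noqa: F821
    delta_aic: float
    delta_bic: float
    delta_deviance: float
    collinear: bool = False


def fit_augmented(
    data: pd.DataFrame,
    decoded: DecodedEstimates,
    variant: str = "RU",
    hierarchical: bool = False,
) -> AugmentedComparison:
    """Fit the augmented probit and compare it to the intercept baseline.

    The decoded series must align with ``data``'s rows (all trials,
    including timeouts, which both fits then exclude). Deltas are
    augmented minus baseline, so negative values favour the augmentation.
    Perfect collinearity between a decoded column and its model-based
    counterpart is flagged.
    """
    from .fit import fit_probit_hierarchical, fit_probit_ml

    if variant not in _VARIANT_POLICY:
        raise ValueError(f"unknown variant {variant!r}; expected {sorted(_VARIANT_POLICY)}")
    aug = data.copy()
    n = len(aug)

    def _aligned(series, name):
        if series is None:
            raise ValueError(f"variant {variant!r} needs decoded {name}")
        series = np.asarray(series, dtype=float)
        if len(series) != n:
            raise ValueError(f"decoded {name} length {len(series)} != {n} trials")
        return series

    if variant in ("RU", "both"):
        aug["RUhat"] = _aligned(decoded.ru_hat, "RU")
    if variant in ("TU", "both"):
        tu_hat = _aligned(decoded.tu_hat, "TU")
        aug["VoverTUhat"] = aug["V"].to_numpy(float) / np.maximum(tu_hat, TU_FLOOR)
    if variant == "DV":
        aug["DVhat"] = _aligned(decoded.dv_hat, "DV")

    fitter = fit_probit_hierarchical if hierarchical else fit_probit_ml
    baseline = fitter(aug, "hybrid", include_intercept=True)
    augmented = fitter(aug, _VARIANT_POLICY[variant], include_intercept=True)

    collinear = False
    pairs = {"RU": [("RUhat", "RU")], "TU": [("VoverTUhat", "VoverTU")],
             "both": [("RUhat", "RU"), ("VoverTUhat", "VoverTU")],
             "DV": [("DVhat", None)]}
    for new_col, old_col in pairs[variant]:
        if old_col is None:
            continue
        a = aug[new_col].to_numpy(float)
        b = aug[old_col].to_numpy(float)
        if np.std(a) > 0 and np.std(b) > 0:
            if abs(np.corrcoef(a, b)[0, 1]) > 1 - 1e-10:
                collinear = True
                augmented.warnings.append(
                    f"decoded column {new_col} is collinear with {old_col}"
                )
    return AugmentedComparison(
        variant=variant,
        baseline=baseline,
        augmented=augmented,
        delta_aic=augmented.aic - baseline.aic,
        delta_bic=augmented.bic - baseline.bic,
        delta_deviance=augmented.deviance - baseline.deviance,
        collinear=collinear,
    )


# ---------------------------------------------------------------------------
# Residual-variance vs TU^2
# ---------------------------------------------------------------------------

@dataclass
class ResidualTUResult:
    """Group test of corr(squared residuals, TU^2)."""

    per_subject_r: pd.Series
    fisher_z: pd.Series
    t: float
    df: int
    p: float
    excluded: list = field(default_factory=list)


def panel_residuals(panel: NeuralPanel) -> np.ndarray:
    """Per-trial residual y - X beta, averaged across the region's voxels."""
    resid = panel.y - panel.X.to_numpy(float) @ panel.beta.T
    return resid.mean(axis=1)


def residual_tu_analysis(per_subject: dict) -> ResidualTUResult:
    """Fisher-z group test of the residual-variance/TU^2 correlation.

    ``per_subject`` maps subject -> (residual series, TU series). For each
    subject the Pearson correlation between squared residuals and TU^2 is
    computed; correlations are Fisher z-transformed and tested against zero
    with a two-tailed one-sample t-test. Subjects with fewer than 3 trials
    or zero-variance inputs are excluded and reported.
    """
    rs, zs, excluded = {}, {}, []
    for subj, (resid, tu) in per_subject.items():
        resid = np.asarray(resid, dtype=float)
        tu = np.asarray(tu, dtype=float)
        if len(resid) != len(tu):
            raise ValueError(f"subject {subj}: residual/TU length mismatch")
        r2 = resid**2
        tu2 = tu**2
        if len(r2) < 3 or np.std(r2) == 0 or np.std(tu2) == 0:
            excluded.append(subj)
            continue
        r = float(np.corrcoef(r2, tu2)[0, 1])
        rs[subj] = r
        zs[subj] = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    if len(zs) < 2:
        raise ValueError("need at least 2 subjects with defined correlations")
    z = pd.Series(zs)
    t_res = stats.ttest_1samp(z.to_numpy(), 0.0)
    return ResidualTUResult(
        per_subject_r=pd.Series(rs),
        fisher_z=z,
        t=float(t_res.statistic),
        df=len(z) - 1,
        p=float(t_res.pvalue),
        excluded=excluded,
    )
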