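"""End-to-end analysis pipeline: simulate -> observe -> fit -> compare ->
decode -> report.

Every stochastic stage consumes a named substream of the master seed, so a
given configuration reproduces its outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from . import io
from .choice_models import Weights
from .fit import (
    fit_condition_model,
    fit_probit_hierarchical,
    fit_probit_ml,
    parameter_recovery,
    performance,
)
from .model_selection import compare_models
from .neural import (
    decode_estimates,
    fit_augmented,
    generate_neural,
    panel_residuals,
    residual_tu_analysis,
)
from .observer import run_observer
from .task import TaskConfig, simulate_dataset


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`."""

    task: TaskConfig = field(default_factory=lambda: TaskConfig(n_subjects=5))
    policy: str = "hybrid"
    # generative weights default to the scale typically recovered from
    # human subjects on this task
    weights: tuple = (0.166, 0.175, 0.005)
    hierarchical: bool = False
    include_intercept: bool = False
    n_recovery_sims: int = 0
    neural: bool = True
    neural_beta: float = 1.0
    neural_noise_sd: float = 1.0
    neural_lam: float = 1.0
    neural_n_voxels: int = 10
    neural_mode: str = "thompson-sample-DV"
    bms_samples: int = 100_000
    outdir: str = "pipeline_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        task = TaskConfig(**raw.pop("task", {}))
        if "weights" in raw:
            raw["weights"] = tuple(raw["weights"])
        return cls(task=task, **raw)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages and write their artifacts under ``cfg.outdir``.

    Returns the report dictionary that is also written as report.json.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    task = replace(cfg.task, seed=int(np.random.SeedSequence([cfg.seed, 1]).generate_state(1)[0] >> 1))
    weights = Weights.from_sequence(cfg.weights)
    report: dict = {"seed": cfg.seed, "task_seed": task.seed}

    # 1. simulate
    trials = simulate_dataset(task, cfg.policy, weights)
    io.write_trials(trials, outdir / "trials.csv")

    # 2. observer regressors (recomputed from the recorded choices)
    regs = run_observer(trials, task)
    io.write_regressors(regs, outdir / "regressors.csv")

    # 3. hybrid fit
    fitter = fit_probit_hierarchical if cfg.hierarchical else fit_probit_ml
    hybrid_fit = fitter(trials, "hybrid", include_intercept=cfg.include_intercept)
    io.write_json(hybrid_fit.to_dict(), outdir / "fit_hybrid.json")
    report["hybrid_fit"] = hybrid_fit.to_dict()
    report["performance"] = performance(trials)

    # 4. condition intercepts/slopes
    cond = fit_condition_model(trials)
    cond.summary.to_csv(outdir / "condition_model.csv", float_format=io.FLOAT_FORMAT)
    report["condition_model"] = {
        j: {k: float(v) for k, v in row.items()}
        for j, row in cond.summary.iterrows()
    }

    # 5. model comparison + BMS
    table, bms, _ = compare_models(
        trials, seed=int(np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0] >> 1),
        n_samples=cfg.bms_samples,
    )
    table.to_csv(outdir / "model_comparison.csv", float_format=io.FLOAT_FORMAT)
    io.write_json(bms.to_dict(), outdir / "bms.json")
    report["bms"] = bms.to_dict()

    # 6. parameter recovery (optional)
    if cfg.n_recovery_sims >= 2:
        rec = parameter_recovery(
            cfg.n_recovery_sims,
            cfg.task,
            seed=int(np.random.SeedSequence([cfg.seed, 3]).generate_state(1)[0] >> 1),
        )
        rec.to_frame().to_csv(outdir / "recovery.csv", index=False, float_format=io.FLOAT_FORMAT)
        report["recovery"] = {
            "per_coef_r": rec.per_coef_r.tolist(),
            "max_abs_pairwise_r": float(
                np.nanmax(np.abs(rec.pairwise_r[~np.eye(3, dtype=bool)]))
            ),
            "n_failed": rec.n_failed,
        }

    # 7. neural decode + augmentation + residual-variance test
    if cfg.neural:
        nseed = int(np.random.SeedSequence([cfg.seed, 4]).generate_state(1)[0] >> 1)
        panel = generate_neural(
            trials,
            encoding={"absRU": cfg.neural_beta, "TU": cfg.neural_beta, "absDV": cfg.neural_beta},
            n_voxels=cfg.neural_n_voxels,
            noise_sd=cfg.neural_noise_sd,
            lam=cfg.neural_lam,
            mode=cfg.neural_mode,
            weights=weights,
            seed=nseed,
        )
        io.write_panel(panel, outdir / "neural_panel")
        decoded = decode_estimates(panel, trials, weights=weights)
        comp = fit_augmented(trials, decoded, variant="RU")
        report["augmented_RU"] = {
            "delta_aic": comp.delta_aic,
            "delta_bic": comp.delta_bic,
            "delta_deviance": comp.delta_deviance,
        }
        resid = panel_residuals(panel)
        per_subject = {
            subj: (resid[idx.to_numpy()], trials.loc[idx, "TU"].to_numpy())
            for subj, idx in trials.groupby("subject").groups.items()
        }
        rt = residual_tu_analysis(per_subject)
        report["residual_tu"] = {"t": rt.t, "df": rt.df, "p": rt.p}

    io.write_json(report, outdir / "report.json")
    return report
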