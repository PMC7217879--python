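"""Readers/writers for the trial, regressor and neural-panel schemas.

All files are plain CSV/JSON. Floats are serialised with 9 significant
digits, enough for reproducibility checks without bit-level fragility.
Indices (subject, run, block, trial) are 1-based in files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .task import CONDITIONS

FLOAT_FORMAT = "%.9g"

TRIALS_COLUMNS = [
    "subject", "run", "block", "condition", "trial",
    "arm1_type", "arm2_type", "mu1", "mu2", "choice", "reward", "timeout",
]

REGRESSORS_COLUMNS = ["subject", "run", "block", "trial", "V", "RU", "TU", "VoverTU"]


class ParseError(ValueError):
    """A schema violation in an input file, with the offending line."""


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write trial records; choice is left empty on timeouts."""
    out = trials[TRIALS_COLUMNS].copy()
    out["choice"] = out["choice"].map(
        lambda c: "" if not np.isfinite(c) else str(int(c))
    )
    out["timeout"] = out["timeout"].astype(bool)
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trials CSV (schema above; header line is 1)."""
    df = pd.read_csv(path, dtype={"condition": str, "arm1_type": str, "arm2_type": str})
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    def _line(i: int) -> int:
        return int(i) + 2  # header + 1-based

    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        i = int(np.nonzero(bad.to_numpy())[0][0])
        raise ParseError(
            f"{path}, line {_line(i)}: invalid condition {df['condition'].iloc[i]!r}"
        )
    for col in ("arm1_type", "arm2_type"):
        bad = ~df[col].isin(("R", "S"))
        if bad.any():
            i = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(f"{path}, line {_line(i)}: invalid {col} {df[col].iloc[i]!r}")
    choice = pd.to_numeric(df["choice"], errors="coerce")
    bad = np.isfinite(choice) & ~choice.isin((1, 2))
    if bad.any():
        i = int(np.nonzero(bad.to_numpy())[0][0])
        raise ParseError(f"{path}, line {_line(i)}: choice must be 1, 2 or empty")
    df["choice"] = choice.astype(float)
    df["timeout"] = df["timeout"].astype(bool)
    bad = df["timeout"].to_numpy() != ~np.isfinite(choice.to_numpy())
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        raise ParseError(
            f"{path}, line {_line(i)}: timeout flag inconsistent with missing choice"
        )
    return df


def write_regressors(regs: pd.DataFrame, path) -> None:
    regs[REGRESSORS_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_regressors(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REGRESSORS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _round_floats(obj, sig: int = 9):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_round_floats(obj), indent=2) + "\n")


def write_panel(panel, prefix) -> None:
    """Write a neural panel as <prefix>.csv (long: trial,voxel,y) plus a
    sidecar <prefix>.json with the design betas and ridge constant."""
    prefix = Path(prefix)
    n, v = panel.y.shape
    long = pd.DataFrame(
        {
            "trial_row": np.repeat(np.arange(1, n + 1), v),
            "voxel": np.tile(np.arange(1, v + 1), n),
            "y": panel.y.ravel(),
        }
    )
    long.to_csv(prefix.with_suffix(".csv"), index=False, float_format=FLOAT_FORMAT)
    side = {
        "columns": panel.columns,
        "beta": panel.beta.tolist(),
        "lam": panel.lam,
        "noise_sd": panel.noise_sd,
        "mode": panel.mode,
    }
    write_json(side, prefix.with_suffix(".json"))
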