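"""Reading and writing of trial tables, workspace configs and matrices.

Trial tables are plain CSV with the exact header
``subject,session,block,trial,angle_deg,velocity_deg_s,error_cm,post_hit``;
matrices (error surfaces, Tolerance and E(R) maps) are delimited text with
a YAML sidecar recording the configuration that produced them.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .subject_stats import TRIAL_COLUMNS
from .task_model import ConfigError, WorkspaceConfig, load_preset, preset_names

__all__ = [
    "TrialTableError",
    "read_trials",
    "write_trials",
    "load_workspace",
    "save_workspace",
    "save_matrix",
    "load_matrix",
]

_NUMERIC = ["session", "block", "trial", "angle_deg", "velocity_deg_s",
            "error_cm", "post_hit"]


class TrialTableError(ValueError):
    """Malformed trial table; message carries file line numbers."""


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Raises :class:`TrialTableError` naming the offending lines for missing
    columns, non-numeric fields, bad post-hit flags or negative errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject": str}, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    df = df[TRIAL_COLUMNS]
    bad_lines: list[int] = []
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
        df[col] = coerced
    if bad_lines:
        raise TrialTableError(
            f"{path}: non-numeric fields on lines {sorted(set(bad_lines))}")
    null = df[["session", "block", "trial", "angle_deg",
               "velocity_deg_s", "post_hit"]].isna().any(axis=1)
    if null.any():
        raise TrialTableError(
            f"{path}: missing required fields on lines {(df.index[null] + 2).tolist()}")
    if not df["post_hit"].isin([0, 1]).all():
        bad = df.index[~df["post_hit"].isin([0, 1])] + 2
        raise TrialTableError(f"{path}: post_hit must be 0/1, lines {bad.tolist()}")
    neg = df["error_cm"] < 0
    if neg.any():
        raise TrialTableError(
            f"{path}: negative error_cm on lines {(df.index[neg] + 2).tolist()}")
    for col in ("session", "block", "trial", "post_hit"):
        df[col] = df[col].astype(int)
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table; ``read_trials`` of the output reproduces it."""
    df = trials[TRIAL_COLUMNS].copy()
    df["post_hit"] = df["post_hit"].astype(int)
    df.to_csv(path, index=False)


def load_workspace(source) -> WorkspaceConfig:
    """Load a workspace from a preset name or a YAML file path."""
    if isinstance(source, WorkspaceConfig):
        return source
    if isinstance(source, str) and source in preset_names():
        return load_preset(source)
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"workspace {source!r} is neither a preset "
                          f"({preset_names()}) nor an existing file")
    d = yaml.safe_load(path.read_text())
    d.setdefault("name", path.stem)
    return WorkspaceConfig.from_dict(d)


def save_workspace(config: WorkspaceConfig, path) -> None:
    d = config.to_dict()
    if math.isinf(d.get("damping_tau", math.inf)):
        d["damping_tau"] = float("inf")
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def save_matrix(matrix: np.ndarray, path, sidecar: dict | None = None) -> None:
    """Write a matrix as delimited text, optionally with a YAML sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(matrix), delimiter=",")
    if sidecar is not None:
        path.with_suffix(path.suffix + ".yaml").write_text(
            yaml.safe_dump(sidecar, sort_keys=False))


def load_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")
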