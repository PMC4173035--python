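"""Configuration and table I/O: flat key-value parameter files (YAML),
delimited-text trajectories and series, JSON records, and run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .delays import DelayBudget
from .errors import InvalidInputError
from .model import WILD_TYPE, ClockParameters, Trajectory

__all__ = [
    "load_config",
    "params_from_config",
    "params_to_config",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "read_series_csv",
    "write_trajectory_json",
    "write_manifest",
]

_PARAM_KEYS = (
    "mrna_synthesis_max",
    "mrna_degradation",
    "protein_synthesis",
    "protein_degradation",
    "repression_threshold",
    "hill_coefficient",
)
_DELAY_KEYS = ("transcription_min", "processing_min", "translation_min")


def load_config(path: str | Path) -> dict:
    """Flat key-value configuration from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"config {path} must be a flat key-value map")
    return cfg


def params_from_config(cfg: dict) -> ClockParameters:
    """Clock parameters from a flat config; unspecified keys default to the
    calibrated wild type."""
    base = WILD_TYPE
    values = {k: float(cfg.get(k, getattr(base, k))) for k in _PARAM_KEYS}
    delay = DelayBudget(
        **{k: float(cfg.get(k, getattr(base.delay, k))) for k in _DELAY_KEYS}
    )
    return ClockParameters(delay=delay, **values)


def params_to_config(params: ClockParameters) -> dict:
    cfg = {k: getattr(params, k) for k in _PARAM_KEYS}
    cfg.update({k: getattr(params.delay, k) for k in _DELAY_KEYS})
    return cfg


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_min": traj.times, "mrna": traj.mrna, "protein": traj.protein}
    )
    df.to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    for col in ("time_min", "mrna", "protein"):
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing column {col!r}")
    return Trajectory(
        df["time_min"].to_numpy(),
        df["mrna"].to_numpy(),
        df["protein"].to_numpy(),
    )


def read_series_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """A (time, value) series from delimited text.

    Accepts either (time_min, value) columns or the first two columns of
    the file.
    """
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise InvalidInputError(f"{path}: need at least two columns")
    if "time_min" in df.columns and "value" in df.columns:
        t, v = df["time_min"], df["value"]
    else:
        t, v = df.iloc[:, 0], df.iloc[:, 1]
    return t.to_numpy(dtype=float), v.to_numpy(dtype=float)


def write_trajectory_json(traj: Trajectory, path: str | Path) -> None:
    payload = {
        "params_fingerprint": traj.params_fingerprint,
        "time_min": traj.times.tolist(),
        "mrna": traj.mrna.tolist(),
        "protein": traj.protein.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def write_manifest(out_dir: str | Path, config: dict) -> Path:
    """Echo the fully resolved run configuration next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"package_version": __version__, **config}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
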