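"""Canonical on-disk formats: trial CSV + JSON sidecar, HDF5 windows,
YAML run configuration.

Layout of a run directory: ``trials/`` (one ``trial_XXXX.csv`` per
trial with a matching ``trial_XXXX.json`` sidecar holding crash times,
seed and simulation parameters), ``windows.h5``, ``models/``,
``reports/`` — plain, diffable files so partial reruns are easy.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .dynamics import SimParams, TrialRecord
from .pilot import PilotParams
from .predictors import ModelSpec
from .preprocess import WindowSet

TRIAL_COLUMNS = ["t", "theta", "omega", "joystick", "control_enabled"]


def write_trial_csv(trial: TrialRecord, csv_path) -> None:
    csv_path = Path(csv_path)
    df = pd.DataFrame({
        "t": trial.t, "theta": trial.theta, "omega": trial.omega,
        "joystick": trial.joystick,
        "control_enabled": trial.control_enabled.astype(int),
    })
    df.to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = {
        "crashes": [float(c) for c in trial.crash_times],
        "seed": trial.seed,
        "params": trial.params.to_dict(),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trial_csv(csv_path) -> TrialRecord:
    """Read a trial; validates schema, uniform timestep and finiteness."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing column(s) {missing}")
    side = csv_path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
        params = SimParams(**meta["params"])
        crashes = list(meta.get("crashes", []))
        seed = meta.get("seed")
    else:
        t = df["t"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else 0.02
        params = SimParams(dt=dt)
        crashes, seed = [], None
    rec = TrialRecord(
        t=df["t"].to_numpy(dtype=float),
        theta=df["theta"].to_numpy(dtype=float),
        omega=df["omega"].to_numpy(dtype=float),
        joystick=df["joystick"].to_numpy(dtype=float),
        control_enabled=df["control_enabled"].to_numpy().astype(bool),
        crash_times=crashes, params=params, seed=seed,
    )
    dt = np.diff(rec.t)
    if len(dt) and not np.allclose(dt, rec.params.dt, rtol=0, atol=1e-9):
        raise ValueError(f"{csv_path}: non-uniform timestep")
    rec.validate()
    return rec


def write_trials(trials: Sequence[TrialRecord], out_dir) -> List[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, trial in enumerate(trials):
        p = out_dir / f"trial_{i:04d}.csv"
        write_trial_csv(trial, p)
        paths.append(p)
    return paths


def read_trials(in_dir) -> List[TrialRecord]:
    paths = sorted(Path(in_dir).glob("trial_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no trial_*.csv under {in_dir}")
    return [read_trial_csv(p) for p in paths]


def save_windows(windows: WindowSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=windows.X, compression="gzip")
        f.create_dataset("y", data=windows.y)
        f.create_dataset("episode_id", data=windows.episode_id)
        f.create_dataset("trial_id", data=windows.trial_id)
        f.create_dataset("end_time", data=windows.end_time)
        f.create_dataset("end_index", data=windows.end_index)
        f.attrs["window_ms"] = windows.window_ms
        f.attrs["advance_ms"] = windows.advance_ms
        f.attrs["stride_steps"] = windows.stride_steps


def load_windows(path) -> WindowSet:
    with h5py.File(path, "r") as f:
        return WindowSet(
            X=f["X"][...], y=f["y"][...],
            episode_id=f["episode_id"][...], trial_id=f["trial_id"][...],
            end_time=f["end_time"][...], end_index=f["end_index"][...],
            window_ms=float(f.attrs["window_ms"]),
            advance_ms=float(f.attrs["advance_ms"]),
            stride_steps=int(f.attrs["stride_steps"]),
        )


def save_model(model, spec: ModelSpec, out_dir) -> Path:
    """Checkpoint: weights as .npz plus a ModelSpec JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p.v for i, p in enumerate(model.params())}
    np.savez(out_dir / "weights.npz", **arrays)
    (out_dir / "spec.json").write_text(json.dumps(spec.to_dict(), indent=1))
    return out_dir


def load_model(model_dir, input_shape) -> tuple:
    """Rebuild a checkpointed model; returns (model, spec)."""
    from .predictors import build_model  # local import avoids a cycle
    model_dir = Path(model_dir)
    spec = ModelSpec(**json.loads((model_dir / "spec.json").read_text()))
    model = build_model(spec, input_shape)
    with np.load(model_dir / "weights.npz") as z:
        for i, p in enumerate(model.params()):
            p.v[...] = z[f"p{i}"]
    return model, spec


@dataclasses.dataclass
class RunConfig:
    """Everything a full pipeline run consumes, serializable to YAML."""

    sim: SimParams = dataclasses.field(default_factory=SimParams)
    n_pilots: int = 10
    trials_per_pilot: int = 4
    difficulty_spread: float = 1.0
    window_ms: float = 1000.0
    advance_ms: float = 800.0
    stride_steps: int = 1
    train_fraction: float = 0.9
    n_folds: int = 10
    target_recall: float = 0.95
    model: ModelSpec = dataclasses.field(default_factory=ModelSpec)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimParams(**d["sim"])
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelSpec(**d["model"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
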