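"""File formats: configs (YAML), trajectories (CSV/Parquet), checkpoints,
run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import TrajectoryBatch
from .model import (AgentNet, GAT3Baseline, GATBaseline, LSTMBaseline,
                    MLPBaseline, ModelConfig, Normalization, RecurrentAgentNet)
from .simulators import AOUPConfig, CAConfig, VicsekConfig
from .training import TrainConfig

_MODEL_CLASSES = {
    "AgentNet": AgentNet,
    "RecurrentAgentNet": RecurrentAgentNet,
    "MLPBaseline": MLPBaseline,
    "LSTMBaseline": LSTMBaseline,
    "GATBaseline": GATBaseline,
    "GAT3Baseline": GAT3Baseline,
}

_SIM_CONFIGS = {"ca": CAConfig, "vicsek": VicsekConfig, "aoup": AOUPConfig}


# -------------------------------------------------------------------- configs
def _build_dataclass(cls, data: dict, label: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {label} key(s): {sorted(unknown)}")
    obj = cls(**data)
    return obj.validate() if hasattr(obj, "validate") else obj


def load_config(path, kind: str):
    """Load and validate a config file.

    kind: 'ca' | 'vicsek' | 'aoup' | 'model' | 'train'.  An empty file
    yields the documented defaults; unknown keys are rejected by name.
    AOUP simulation configs must pin the interaction length: provide 'R'
    (single run) or 'r_range' (dataset generation).
    """
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    if kind == "model":
        system = data.pop("system", "ca")
        return ModelConfig.for_system(system, **data)
    if kind == "train":
        return _build_dataclass(TrainConfig, data, "training config")
    if kind in _SIM_CONFIGS:
        if kind == "aoup":
            r_range = data.pop("r_range", None)
            if r_range is None and "R" not in data:
                raise ValueError(
                    "AOUP config needs 'R' (single run) or 'r_range' "
                    "(e.g. r_range: [2.0, 4.0]) to pin the interaction length"
                )
            cfg = _build_dataclass(AOUPConfig, data, "aoup config")
            cfg.validate()
            return (cfg, tuple(r_range)) if r_range is not None else cfg
        return _build_dataclass(_SIM_CONFIGS[kind], data, f"{kind} config")
    raise ValueError(f"unknown config kind '{kind}'")


def save_config(obj, path) -> None:
    d = obj.to_dict() if hasattr(obj, "to_dict") else dataclasses.asdict(obj)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------- trajectories
def write_trajectories(batch: TrajectoryBatch, path) -> Path:
    """Write the long-format trajectory table plus a YAML sidecar.

    CSV for plain-text output, Parquet ('.parquet') for large sets.
    """
    path = Path(path)
    df = batch.to_frame()
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        # %.17g keeps the CSV round trip lossless for float64 states
        df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "var_names": list(batch.var_names),
        "global_names": list(batch.global_names),
        "globals": None if batch.globals_ is None else batch.globals_.tolist(),
    }
    path.with_suffix(path.suffix + ".meta.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=False)
    )
    return path


def read_trajectories(path) -> TrajectoryBatch:
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    var_names, globals_, global_names = None, None, ()
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        var_names = tuple(meta.get("var_names") or ()) or None
        global_names = tuple(meta.get("global_names") or ())
        if meta.get("globals") is not None:
            globals_ = np.asarray(meta["globals"], dtype=float)
    return TrajectoryBatch.from_frame(df, var_names=var_names,
                                      globals_=globals_,
                                      global_names=global_names)


# ----------------------------------------------------------------- checkpoints
def save_checkpoint(model, path, extra: dict | None = None) -> Path:
    """Weights + model config + normalization statistics, versioned."""
    path = Path(path)
    meta = {
        "format_version": 1,
        "package_version": __version__,
        "model_class": type(model).__name__,
        "config": model.cfg.to_dict(),
        "extra": extra or {},
    }
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), norm_mean=model.norm.mean,
             norm_std=model.norm.std, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(
        path.suffix + ".npz")


def load_checkpoint(path):
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        cfg = ModelConfig.from_dict(meta["config"])
        cls = _MODEL_CLASSES[meta["model_class"]]
        model = cls(cfg)
        n_params = sum(1 for k in z.files if k.startswith("param_"))
        model.load_arrays([z[f"param_{i}"] for i in range(n_params)])
        model.set_normalization(Normalization(z["norm_mean"], z["norm_std"]))
    return model, meta


# -------------------------------------------------------------------- manifest
def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


class RunManifest:
    """Reproducibility record written by every CLI command."""

    def __init__(self, command: str, seed: int | None, config: dict | None):
        self.data = {
            "command": command,
            "seed": seed,
            "config": config,
            "package_version": __version__,
            "inputs": {},
            "outputs": {},
            "started": time.time(),
        }

    def add_input(self, path) -> None:
        self.data["inputs"][str(path)] = file_digest(path)

    def add_output(self, path) -> None:
        self.data["outputs"][str(path)] = file_digest(path)

    def write(self, path) -> Path:
        self.data["elapsed_s"] = round(time.time() - self.data["started"], 3)
        p = Path(path)
        p.write_text(json.dumps(self.data, indent=2, default=str))
        return p
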