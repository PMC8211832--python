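"""Model configuration and per-system presets.

Presets: attention (key/query/value) width 16 for the simulated systems
and 96 for the swift-like spatiotemporal setting; encoders
[input, 256, 3 x attention]; one attention MLP and one decoder per
output variable; Gaussian heads [decoder out, 64, 1] for stochastic
systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class ModelConfig:
    system: str = "ca"
    input_dims: int = 3
    n_out_vars: int = 1                  # number of predicted state variables
    att_dims: int = 16                   # key/query/value width
    att_mlp: tuple[int, ...] = (32, 32, 16, 1)
    encoder_hidden: int = 256
    decoder_hidden: int = 128
    decoder_out: int = 1                 # width of each per-variable decoder output
    head_hidden: int = 64
    n_globals: int = 0
    stochastic: bool = False
    recurrent: bool = False
    lstm_hidden: int = 128
    target_var_indices: tuple[int, ...] = (2,)  # which input vars are predicted
    per_variable_decoder: bool = True
    dedupe_pairs: bool = False           # reuse attention rows for repeated states
    att_bias_init: float = 0.0           # initial attention-coefficient bias
    dtype: str = "float64"

    def validate(self) -> "ModelConfig":
        expected = 2 * self.att_dims + self.n_globals
        if self.att_mlp[0] != expected:
            raise ValueError(
                f"att_mlp input width {self.att_mlp[0]} != 2*att_dims+n_globals"
                f" = {expected}"
            )
        if self.att_mlp[-1] != 1:
            raise ValueError("att_mlp must end in a single attention coefficient")
        if self.stochastic and len(self.target_var_indices) != self.n_out_vars:
            raise ValueError("target_var_indices must name one input var per output")
        if self.n_out_vars < 1 or self.input_dims < 1 or self.att_dims < 1:
            raise ValueError("dimensions must be positive")
        return self

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["att_mlp"] = list(self.att_mlp)
        d["target_var_indices"] = list(self.target_var_indices)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["att_mlp"] = tuple(d["att_mlp"])
        d["target_var_indices"] = tuple(d["target_var_indices"])
        return cls(**d).validate()

    @classmethod
    def for_system(cls, system: str, **overrides) -> "ModelConfig":
        presets = {
            "ca": dict(
                system="ca", input_dims=3, n_out_vars=1, att_dims=16,
                att_mlp=(32, 32, 16, 1), decoder_out=1, stochastic=False,
                recurrent=False, target_var_indices=(2,), dedupe_pairs=True,
                att_bias_init=-2.0,
            ),
            "vicsek": dict(
                system="vicsek", input_dims=4, n_out_vars=2, att_dims=16,
                att_mlp=(32, 64, 32, 1), decoder_out=2, stochastic=True,
                recurrent=False, target_var_indices=(0, 1),
            ),
            "aoup": dict(
                system="aoup", input_dims=4, n_out_vars=4, att_dims=16,
                att_mlp=(33, 16, 8, 1), decoder_out=4, stochastic=True,
                recurrent=True, n_globals=1, target_var_indices=(0, 1, 2, 3),
            ),
            "swift": dict(
                system="swift", input_dims=7, n_out_vars=6, att_dims=96,
                att_mlp=(192, 16, 8, 1), decoder_out=6, stochastic=True,
                recurrent=True, target_var_indices=(0, 1, 2, 3, 4, 5),
            ),
        }
        if system not in presets:
            raise ValueError(f"unknown system '{system}'")
        cfg = dict(presets[system])
        cfg.update(overrides)
        return cls(**cfg).validate()


@dataclass
class Normalization:
    """Per-variable standardization statistics stored with a model."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        self.std = np.where(self.std > 0, self.std, 1.0)

    @classmethod
    def identity(cls, dims: int) -> "Normalization":
        return cls(np.zeros(dims), np.ones(dims))

    @classmethod
    def fit(cls, states: np.ndarray) -> "Normalization":
        flat = states.reshape(-1, states.shape[-1])
        return cls(flat.mean(axis=0), flat.std(axis=0))

    def apply(self, states: np.ndarray) -> np.ndarray:
        return (states - self.mean) / self.std

    def invert(self, states: np.ndarray, idx=None) -> np.ndarray:
        if idx is None:
            return states * self.std + self.mean
        return states * self.std[list(idx)] + self.mean[list(idx)]
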