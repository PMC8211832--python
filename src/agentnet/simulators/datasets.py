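"""Training-set generation for the three ground-truth systems.

Each sample is an input/target pair in the shape the corresponding model
variant consumes:

* CA — one-step grid transitions (cell states -> next alive flags);
* Vicsek — one-step transitions (agent states -> next positions), agents
  initially scattered in a disk of radius sqrt(5);
* AOUP — windows of 8 observed steps followed by 12 target steps, with the
  interaction length R drawn per sample from a training range (default
  [2, 4]) and exported as a global variable; the propulsion force is a
  hidden variable and is never exported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..data import TrajectoryBatch
from ..utils import rng_from
from . import aoup as aoup_mod
from . import ca as ca_mod
from . import vicsek as vicsek_mod


@dataclass
class CADataset:
    inputs: np.ndarray    # (S, n_cells, 3): x, y, c
    labels: np.ndarray    # (S, n_cells): next alive flag
    config: ca_mod.CAConfig

    def __len__(self):
        return self.inputs.shape[0]


@dataclass
class VicsekDataset:
    inputs: np.ndarray      # (S, n, 4): x, y, v_x, v_y
    targets: np.ndarray     # (S, n, 2): next x, y
    membership: np.ndarray  # (S, n, n) ground-truth R_i membership
    config: vicsek_mod.VicsekConfig

    def __len__(self):
        return self.inputs.shape[0]


@dataclass
class AOUPDataset:
    inputs: np.ndarray    # (S, T_obs, n, 4): x, y, v_x, v_y
    targets: np.ndarray   # (S, T_pred, n, 4)
    R: np.ndarray         # (S,) global interaction length per sample
    config: aoup_mod.AOUPConfig

    T_OBS = 8
    T_PRED = 12

    def __len__(self):
        return self.inputs.shape[0]


def generate_ca(config: ca_mod.CAConfig, n_samples: int, seed: int) -> CADataset:
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    config = config.validate()
    rng = rng_from(seed, "ca-dataset")
    inputs, labels = [], []
    for _ in range(n_samples):
        grid = ca_mod.random_grid(rng, config)
        nxt = ca_mod.ca_step(grid)
        inputs.append(grid.as_states())
        labels.append(nxt.state.ravel().astype(float))
    return CADataset(np.asarray(inputs), np.asarray(labels), config)


def generate_vicsek(config: vicsek_mod.VicsekConfig, n_samples: int, seed: int,
                    warm_steps: int = 1) -> VicsekDataset:
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    config = config.validate()
    rng = rng_from(seed, "vicsek-dataset")
    inputs, targets, member = [], [], []
    for _ in range(n_samples):
        state = vicsek_mod.initial_state(rng, config)
        for _ in range(warm_steps):
            state = vicsek_mod.vicsek_step(state, rng)
        nxt = vicsek_mod.vicsek_step(state, rng)
        inputs.append(state.as_states())
        targets.append(nxt.x.copy())
        member.append(vicsek_mod.neighbor_matrix(state))
    return VicsekDataset(np.asarray(inputs), np.asarray(targets),
                         np.asarray(member), config)


def generate_aoup(config: aoup_mod.AOUPConfig, n_samples: int, seed: int,
                  r_range: tuple[float, float] = (2.0, 4.0),
                  burn_in: int = 100) -> AOUPDataset:
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    config = config.validate()
    rng = rng_from(seed, "aoup-dataset")
    T = AOUPDataset.T_OBS + AOUPDataset.T_PRED
    inputs, targets, Rs = [], [], []
    for _ in range(n_samples):
        R = float(rng.uniform(*r_range))
        cfg = replace(config, R=R)
        state = aoup_mod.initial_state(rng, cfg)
        for _ in range(burn_in):
            state = aoup_mod.aoup_step(state, rng)
        window = []
        for _ in range(T):
            state = aoup_mod.aoup_step(state, rng)
            window.append(state.as_states())
        window = np.asarray(window)          # (T, n, 4)
        inputs.append(window[: AOUPDataset.T_OBS])
        targets.append(window[AOUPDataset.T_OBS:])
        Rs.append(R)
    return AOUPDataset(np.asarray(inputs), np.asarray(targets),
                       np.asarray(Rs), config)


def generate_dataset(system: str, config, n_samples: int, seed: int, **kw):
    """Dispatch to the per-system generator ('ca' | 'vicsek' | 'aoup')."""
    gens = {"ca": generate_ca, "vicsek": generate_vicsek, "aoup": generate_aoup}
    if system not in gens:
        raise ValueError(f"unknown system '{system}'")
    return gens[system](config, n_samples, seed, **kw)


def dataset_to_batch(dataset) -> TrajectoryBatch:
    """Convert a training dataset to the tabular TrajectoryBatch container."""
    if isinstance(dataset, CADataset):
        first = dataset.inputs
        second = first.copy()
        second[..., 2] = dataset.labels
        states = np.stack([first, second], axis=1)
        return TrajectoryBatch(states=states, var_names=("x", "y", "c"))
    if isinstance(dataset, VicsekDataset):
        nxt = np.concatenate(
            [dataset.targets, dataset.targets - dataset.inputs[..., :2]], axis=-1
        )
        states = np.stack([dataset.inputs, nxt], axis=1)
        return TrajectoryBatch(states=states, var_names=("x", "y", "v_x", "v_y"))
    if isinstance(dataset, AOUPDataset):
        states = np.concatenate([dataset.inputs, dataset.targets], axis=1)
        return TrajectoryBatch(states=states, var_names=("x", "y", "v_x", "v_y"),
                               globals_=dataset.R[:, None], global_names=("R",))
    raise TypeError(f"unsupported dataset type {type(dataset).__name__}")


def batch_to_dataset(system: str, batch: TrajectoryBatch, config=None):
    """Rebuild a training dataset from the tabular trajectory container."""
    if system == "ca":
        config = config or ca_mod.CAConfig()
        inputs = batch.states[:, 0]
        labels = batch.states[:, 1, :, 2]
        return CADataset(inputs, labels, config)
    if system == "vicsek":
        config = config or vicsek_mod.VicsekConfig(
            n_agents=batch.states.shape[2])
        inputs = batch.states[:, 0]
        targets = batch.states[:, 1, :, :2]
        member = np.stack([
            vicsek_mod.neighbor_matrix(
                vicsek_mod.VicsekState(x=s[:, :2], v=s[:, 2:], config=config))
            for s in inputs
        ])
        return VicsekDataset(inputs, targets, member, config)
    if system == "aoup":
        config = config or aoup_mod.AOUPConfig(
            n_particles=batch.states.shape[2])
        T_obs = AOUPDataset.T_OBS
        if batch.states.shape[1] != T_obs + AOUPDataset.T_PRED:
            raise ValueError("AOUP batches must hold 8 observed + 12 target steps")
        if batch.globals_ is None:
            raise ValueError("AOUP batches must carry the global variable R")
        return AOUPDataset(batch.states[:, :T_obs], batch.states[:, T_obs:],
                           batch.globals_[:, 0], config)
    raise ValueError(f"unknown system '{system}'")
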