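"""Dynamic-node machinery for spatiotemporal graphs.

Real tracking data (e.g. birds filmed by a fixed camera) yields
trajectories that begin and end mid-sequence: agents appear, persist for
a while and disappear.  This module maintains a per-agent registry of
recurrent hidden states so a recurrent AgentNet can run over such data:
agents entering the scene start a fresh hidden-state chain initialized by
dedicated MLPs from their first observed state; present agents advance
their chain; absent agents are excluded from attention aggregation and
from the loss.  By default a reappearing agent resumes its stored chain
(`resume_on_reappear=False` starts a fresh one instead).

`synth_occlusion` imposes synthetic presence intervals on fully observed
simulator output so that this machinery can be exercised and tested
without any empirical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TrajectoryBatch
from .model import RecurrentAgentNet
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .training import length_weights, loss_nll_gaussian
from .utils import rng_from


@dataclass
class RegistryEntry:
    h: Tensor            # (1, 1, H)
    c: Tensor            # (1, 1, H)
    last_seen: int


class HiddenRegistry:
    """Map agent_id -> recurrent (hidden, cell) state and last-seen step."""

    def __init__(self):
        self.entries: dict[int, RegistryEntry] = {}

    def __contains__(self, agent_id: int) -> bool:
        return int(agent_id) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, agent_id: int) -> RegistryEntry:
        return self.entries[int(agent_id)]

    def put(self, agent_id: int, h: Tensor, c: Tensor, step: int) -> None:
        self.entries[int(agent_id)] = RegistryEntry(h, c, step)


def init_hidden(model: RecurrentAgentNet, first_states: np.ndarray,
                registry: HiddenRegistry | None = None,
                agent_ids=None, step: int | None = None):
    """Fresh hidden/cell chains from first observed states via the init MLPs.

    If a registry is given, re-initializing an agent that is currently
    present (seen at `step`) is rejected.
    """
    first_states = np.atleast_2d(np.asarray(first_states, dtype=float))
    if registry is not None and agent_ids is not None:
        for a in np.atleast_1d(agent_ids):
            if a in registry and step is not None \
                    and registry.get(a).last_seen == step:
                raise ValueError(f"agent {int(a)} is present; cannot re-initialize")
    Xn = Tensor(model.normalize(first_states)[None])     # (1, P, d)
    return model.init_hidden(Xn)


class DynGraphRunner:
    """Steps a recurrent AgentNet over frames with a changing agent roster."""

    def __init__(self, model: RecurrentAgentNet,
                 resume_on_reappear: bool = True):
        self.model = model
        self.registry = HiddenRegistry()
        self.resume_on_reappear = resume_on_reappear
        self.t = -1

    def step(self, states: np.ndarray, present: np.ndarray,
             globals_=None):
        """Advance one frame.

        states: (N_roster, d) states for the full roster (absent rows are
        ignored); present: (N_roster,) boolean mask.  Returns the
        prediction for the present agents (roster order) or None if no
        agent is present.
        """
        self.t += 1
        states = np.asarray(states, dtype=float)
        present = np.asarray(present, dtype=bool)
        if states.shape[0] != present.shape[0]:
            raise ValueError("states and presence mask disagree on roster size")
        if not np.isfinite(states[present]).all():
            raise ValueError("present agents carry non-finite states")
        ids = np.flatnonzero(present)
        if ids.size == 0:
            return None
        model = self.model
        Xn = model.normalize(states[ids])                  # (P, d)
        Xt = Tensor(Xn[None])                              # (1, P, d)
        is_new = np.array([
            (a not in self.registry) or not self.resume_on_reappear
            for a in ids
        ])
        if is_new.any():
            new_pos = np.flatnonzero(is_new)
            h_init, c_init = model.init_hidden(Xt[:, new_pos])
        rows_h, rows_c = [], []
        new_cursor = 0
        for pos, a in enumerate(ids):
            if is_new[pos]:
                rows_h.append(h_init[:, new_cursor:new_cursor + 1])
                rows_c.append(c_init[:, new_cursor:new_cursor + 1])
                new_cursor += 1
            else:
                e = self.registry.get(a)
                rows_h.append(e.h)
                rows_c.append(e.c)
        h_prev = rows_h[0] if len(rows_h) == 1 else ad.concat(rows_h, axis=1)
        c_prev = rows_c[0] if len(rows_c) == 1 else ad.concat(rows_c, axis=1)
        h, c = model.encode_step(Xt, h_prev, c_prev)
        for pos, a in enumerate(ids):
            self.registry.put(a, h[:, pos:pos + 1], c[:, pos:pos + 1], self.t)
        self._current = (h, ids, globals_)
        return self.predict_current()

    def predict_current(self):
        h, ids, globals_ = self._current
        res = self.model.predict(h, globals_)
        res.agent_ids = ids
        return res


def step_registry(model: RecurrentAgentNet, runner: DynGraphRunner,
                  states: np.ndarray, present: np.ndarray, globals_=None):
    """Functional wrapper over :meth:`DynGraphRunner.step`."""
    result = runner.step(states, present, globals_)
    return runner.registry, result


# ------------------------------------------------------------- sequence loss
def sequence_nll(model: RecurrentAgentNet, states: np.ndarray,
                 present: np.ndarray, globals_=None,
                 weight_by_length: bool = False,
                 resume_on_reappear: bool = True):
    """Gaussian NLL over a dynamic-node sequence.

    states: (T, N, d); present: (T, N).  The loss at step t covers agents
    present at both t and t+1; absent agents contribute nothing.  With
    `weight_by_length`, per-agent losses are weighted inversely to the
    frequency of their trajectory-length class.
    """
    states = np.asarray(states, dtype=float)
    present = np.asarray(present, dtype=bool)
    T, N, _ = states.shape
    runner = DynGraphRunner(model, resume_on_reappear=resume_on_reappear)
    idx = list(model.cfg.target_var_indices)
    if weight_by_length:
        lengths = present.sum(axis=0)
        w_all = np.ones(N)
        seen = lengths > 0
        w_all[seen] = length_weights(lengths[seen])
    total = None
    weight_sum = 0.0
    for t in range(T):
        res = runner.step(states[t], present[t], globals_)
        if t == T - 1 or res is None:
            continue
        both = present[t] & present[t + 1]
        if not both.any():
            continue
        ids_t = np.flatnonzero(present[t])
        sel = np.flatnonzero(np.isin(ids_t, np.flatnonzero(both)))
        tgt = states[t + 1][both][:, idx]
        tgt_n = (tgt - model.norm.mean[idx]) / model.norm.std[idx]
        mu_sel = res.mu[0][sel]
        var_sel = res.var[0][sel]
        nll = 0.5 * ad.log(2.0 * np.pi * var_sel) \
            + ad.square(Tensor(tgt_n) - mu_sel) / (2.0 * var_sel)
        per_agent = nll.sum(axis=-1)                     # (P_sel,)
        w = (w_all[both] if weight_by_length else np.ones(both.sum()))
        contrib = (per_agent * Tensor(w)).sum()
        total = contrib if total is None else total + contrib
        weight_sum += float(w.sum())
    if total is None:
        raise ValueError("sequence contains no consecutive presence pairs")
    return total / weight_sum


# ------------------------------------------------------------ synthetic masks
@dataclass
class OcclusionConfig:
    """Synthetic presence intervals mimicking camera occlusion.

    Interval lengths are geometric with the given median (about half the
    trajectories shorter than it); `rate` is the fraction of agents that
    get occluded at all.  `contiguous=False` additionally punches random
    single-step holes to stress-test non-contiguous presence.
    """

    median_length: int = 8
    rate: float = 1.0
    contiguous: bool = True

    def validate(self) -> "OcclusionConfig":
        if self.median_length < 1:
            raise ValueError("median_length must be >= 1")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must lie in [0, 1]")
        return self


def synth_occlusion(batch: TrajectoryBatch, config: OcclusionConfig,
                    seed: int = 0) -> TrajectoryBatch:
    """Return a copy of `batch` with synthetic presence intervals."""
    config.validate()
    rng = rng_from(seed, "occlusion")
    S, T, N = batch.present.shape
    present = np.ones((S, T, N), dtype=bool)
    if config.rate > 0:
        p_geom = 1.0 - 0.5 ** (1.0 / config.median_length)
        for s in range(S):
            for a in range(N):
                if rng.random() >= config.rate:
                    continue
                length = min(int(rng.geometric(p_geom)), T)
                start = int(rng.integers(0, T - length + 1))
                mask = np.zeros(T, dtype=bool)
                mask[start:start + length] = True
                if not config.contiguous and length > 2:
                    hole = int(rng.integers(start + 1, start + length - 1))
                    mask[hole] = False
                present[s, :, a] = mask
    return TrajectoryBatch(
        states=batch.states.copy(), var_names=batch.var_names,
        present=present & batch.present,
        globals_=None if batch.globals_ is None else batch.globals_.copy(),
        global_names=batch.global_names,
    )
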