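"""Core trajectory containers shared by simulators, models and IO.

An :class:`AgentStateFrame` is the state of every agent at one time step
plus any global variables (e.g. the soft-core interaction length R).  A
:class:`TrajectoryBatch` stacks frames over time and samples, with a
presence mask so that agents may enter and leave mid-sequence (dynamic
nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AgentStateFrame:
    """States of all agents present at one time step.

    states: (n_agents, n_vars) float array, one row per agent.
    globals_: (n_globals,) float array of system-wide variables.
    """

    states: np.ndarray
    var_names: tuple[str, ...]
    globals_: np.ndarray | None = None
    agent_ids: np.ndarray | None = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[1] != len(self.var_names):
            raise ValueError("states must be (n_agents, n_vars)")
        if self.agent_ids is None:
            self.agent_ids = np.arange(self.states.shape[0])

    @property
    def n_agents(self) -> int:
        return self.states.shape[0]


@dataclass
class TrajectoryBatch:
    """Time-indexed agent states with presence masks.

    states: (n_samples, n_steps, n_agents, n_vars)
    present: (n_samples, n_steps, n_agents) boolean mask
    globals_: (n_samples, n_globals) or None
    """

    states: np.ndarray
    var_names: tuple[str, ...]
    present: np.ndarray | None = None
    globals_: np.ndarray | None = None
    global_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 4:
            raise ValueError("states must be (n_samples, n_steps, n_agents, n_vars)")
        if self.states.shape[3] != len(self.var_names):
            raise ValueError("var_names length must match the last states axis")
        if self.present is None:
            self.present = np.ones(self.states.shape[:3], dtype=bool)
        else:
            self.present = np.asarray(self.present, dtype=bool)
            if self.present.shape != self.states.shape[:3]:
                raise ValueError("present mask must be (n_samples, n_steps, n_agents)")
        if self.globals_ is not None:
            self.globals_ = np.atleast_2d(np.asarray(self.globals_, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def n_steps(self) -> int:
        return self.states.shape[1]

    @property
    def n_agents(self) -> int:
        return self.states.shape[2]

    def frame(self, sample: int, step: int) -> AgentStateFrame:
        mask = self.present[sample, step]
        g = None if self.globals_ is None else self.globals_[sample]
        return AgentStateFrame(
            states=self.states[sample, step][mask],
            var_names=self.var_names,
            globals_=g,
            agent_ids=np.flatnonzero(mask),
        )

    # ------------------------------------------------------------- tabular IO
    def to_frame(self) -> pd.DataFrame:
        """Long-format table: (sample_id, t, agent_id, vars..., present_flag)."""
        S, T, N, K = self.states.shape
        sample_id = np.repeat(np.arange(S), T * N)
        t = np.tile(np.repeat(np.arange(T), N), S)
        agent_id = np.tile(np.arange(N), S * T)
        data = {
            "sample_id": sample_id,
            "t": t,
            "agent_id": agent_id,
        }
        flat = self.states.reshape(-1, K)
        for k, name in enumerate(self.var_names):
            data[name] = flat[:, k]
        data["present_flag"] = self.present.reshape(-1).astype(np.int8)
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, var_names=None,
                   globals_=None, global_names=()) -> "TrajectoryBatch":
        required = {"sample_id", "t", "agent_id", "present_flag"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if var_names is None:
            var_names = tuple(
                c for c in df.columns
                if c not in ("sample_id", "t", "agent_id", "present_flag")
            )
        df = df.sort_values(["sample_id", "t", "agent_id"], kind="stable")
        samples = df["sample_id"].to_numpy()
        ts = df["t"].to_numpy()
        agents = df["agent_id"].to_numpy()
        S = int(samples.max()) + 1
        T = int(ts.max()) + 1
        N = int(agents.max()) + 1
        for s in np.unique(samples):
            t_s = np.unique(ts[samples == s])
            if not np.array_equal(t_s, np.arange(len(t_s))):
                raise ValueError(f"non-contiguous time index in sample {s}")
        states = np.zeros((S, T, N, len(var_names)))
        present = np.zeros((S, T, N), dtype=bool)
        idx = (samples, ts, agents)
        for k, name in enumerate(var_names):
            states[..., k][idx] = df[name].to_numpy()
        present[idx] = df["present_flag"].to_numpy().astype(bool)
        return cls(states=states, var_names=tuple(var_names), present=present,
                   globals_=globals_, global_names=tuple(global_names))
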