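"""Vision-sector Vicsek model.

Each agent replaces its velocity with the average over itself and the
agents inside its vision sector (distance < r_c and bearing within the
cone), plus independent Gaussian noise per component, then moves by the
new velocity.  The sector models an organism's limited field of view: by
default theta_c is the half-angle of the cone, so theta_c = 120 degrees
means a 240-degree field of view (config switch `sector_is_full_angle`
selects the other reading).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class VicsekConfig:
    n_agents: int = 300
    r_c: float = 1.0          # interaction radius, m
    theta_c: float = 120.0    # vision half-angle, degrees (see module docstring)
    sigma: float = 0.1        # noise std per velocity component, m/step
    speed: float = 0.5        # initial speed, m/step
    init_radius: float = float(np.sqrt(5.0))  # initial positions in this disk
    sector_is_full_angle: bool = False

    def validate(self) -> "VicsekConfig":
        if self.n_agents < 1:
            raise ValueError("n_agents must be positive")
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if not 0 < self.theta_c <= 360:
            raise ValueError("theta_c must lie in (0, 360] degrees")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        return self

    @property
    def half_angle_rad(self) -> float:
        deg = self.theta_c / 2.0 if self.sector_is_full_angle else self.theta_c
        return float(np.deg2rad(deg))


@dataclass
class VicsekState:
    """Positions and velocities of all agents, shape (n, 2) each."""

    x: np.ndarray
    v: np.ndarray
    config: VicsekConfig = field(default_factory=VicsekConfig)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.x.shape != self.v.shape or self.x.ndim != 2 or self.x.shape[1] != 2:
            raise ValueError("x and v must both be (n, 2)")

    @property
    def n_agents(self) -> int:
        return self.x.shape[0]

    def as_states(self) -> np.ndarray:
        """Per-agent rows (x, y, v_x, v_y)."""
        return np.hstack([self.x, self.v])


def initial_state(rng: np.random.Generator,
                  config: VicsekConfig | None = None) -> VicsekState:
    """Agents uniform in a disk of radius `init_radius`, random headings."""
    config = (config or VicsekConfig()).validate()
    n = config.n_agents
    r = config.init_radius * np.sqrt(rng.random(n))
    phi = rng.uniform(0, 2 * np.pi, n)
    x = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    heading = rng.uniform(0, 2 * np.pi, n)
    v = config.speed * np.column_stack([np.cos(heading), np.sin(heading)])
    return VicsekState(x=x, v=v, config=config)


def neighbor_matrix(state: VicsekState) -> np.ndarray:
    """(n, n) boolean membership: j in R_i (diagonal False).

    j is a neighbor of i when the distance is < r_c and the bearing of j
    relative to i's heading lies strictly inside the vision cone.  An agent
    with zero speed has no defined heading and sees nobody.
    """
    cfg = state.config
    dx = state.x[None, :, :] - state.x[:, None, :]   # [i, j] = x_j - x_i
    dist = np.linalg.norm(dx, axis=-1)
    speed = np.linalg.norm(state.v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        heading = np.arctan2(state.v[:, 1], state.v[:, 0])
    bearing = np.arctan2(dx[..., 1], dx[..., 0]) - heading[:, None]
    bearing = (bearing + np.pi) % (2 * np.pi) - np.pi
    mask = (dist < cfg.r_c) & (np.abs(bearing) < cfg.half_angle_rad)
    mask &= speed[:, None] > 0.0
    np.fill_diagonal(mask, False)
    return mask


def vicsek_neighbors(state: VicsekState, i: int) -> np.ndarray:
    """Indices of the agents in R_i."""
    return np.flatnonzero(neighbor_matrix(state)[i])


def vicsek_step(state: VicsekState,
                rng: np.random.Generator | None = None) -> VicsekState:
    """One update: velocity <- sector average (self included) + noise,
    position <- position + new velocity."""
    cfg = state.config
    mask = neighbor_matrix(state)
    counts = mask.sum(axis=1)                     # |R_i|
    summed = mask.astype(float) @ state.v + state.v
    v_new = summed / (counts + 1)[:, None]
    if cfg.sigma > 0:
        if rng is None:
            raise ValueError("rng required when sigma > 0")
        v_new = v_new + rng.normal(0.0, cfg.sigma, size=v_new.shape)
    return VicsekState(x=state.x + v_new, v=v_new, config=cfg)


def simulate(config: VicsekConfig, n_steps: int,
             rng: np.random.Generator) -> list[VicsekState]:
    """Full trajectory: initial state plus `n_steps` updates."""
    states = [initial_state(rng, config)]
    for _ in range(n_steps):
        states.append(vicsek_step(states[-1], rng))
    return states
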