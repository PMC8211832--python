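"""Active Ornstein-Uhlenbeck particles with soft-core repulsion.

Overdamped Langevin dynamics for positions x_i,

    gamma * dx/dt = F_ext + F_int + sqrt(2 gamma T) eta + gamma f,

with harmonic confinement F_ext = -k x, pair repulsion from the soft-core
potential V = exp(-r^3 / R^3) (interaction length R, a global variable),
and a hidden propulsion force f following an Ornstein-Uhlenbeck process

    tau * df/dt = -f + sqrt(2 D_a) w.

Euler-Maruyama integration with step dt; the stored velocity is the
per-step displacement (x_{t+dt} = x_t + v_{t+dt}).  The propulsion f is an
internal variable and is never exported to training data.  The stationary
propulsion magnitude satisfies E|f|^2 = 2 D_a / tau = U_0^2.

At high density and low temperature the system relaxes to a cluster
crystal whose hexagonal lattice constant is about 1.4 R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AOUPConfig:
    n_particles: int = 50
    gamma: float = 1.0      # drag coefficient
    T: float = 1.0          # temperature
    tau: float = 1.0        # propulsion correlation time
    D_a: float = 1.0        # active diffusion constant
    k: float = 0.1          # harmonic spring constant
    R: float = 3.0          # soft-core interaction length (global variable)
    dt: float = 0.05        # integration step
    init_radius: float | None = None  # default: dense disk, ~2 particles/site

    def validate(self) -> "AOUPConfig":
        for name in ("gamma", "tau", "dt", "R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("T", "D_a", "k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_particles < 1:
            raise ValueError("n_particles must be positive")
        return self

    @property
    def U0_sq(self) -> float:
        """Squared stationary propulsion norm, U_0^2 = 2 D_a / tau."""
        return 2.0 * self.D_a / self.tau

    def default_init_radius(self) -> float:
        if self.init_radius is not None:
            return self.init_radius
        # two particles per hexagonal site of spacing 1.4 R
        site_area = np.sqrt(3.0) / 2.0 * (1.4 * self.R) ** 2
        return float(np.sqrt(self.n_particles / 2.0 * site_area / np.pi))


@dataclass
class AOUPState:
    """Positions, per-step velocities and hidden propulsion, (n, 2) each."""

    x: np.ndarray
    v: np.ndarray
    f: np.ndarray
    config: AOUPConfig = field(default_factory=AOUPConfig)

    def __post_init__(self):
        for name in ("x", "v", "f"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
        if not (self.x.shape == self.v.shape == self.f.shape) or self.x.ndim != 2:
            raise ValueError("x, v, f must all be (n, 2)")

    @property
    def n_particles(self) -> int:
        return self.x.shape[0]

    def as_states(self) -> np.ndarray:
        """Observable per-particle rows (x, y, v_x, v_y); f stays hidden."""
        return np.hstack([self.x, self.v])


def initial_state(rng: np.random.Generator,
                  config: AOUPConfig | None = None) -> AOUPState:
    """Particles uniform in a dense disk; propulsion drawn stationary."""
    config = (config or AOUPConfig()).validate()
    n = config.n_particles
    radius = config.default_init_radius()
    r = radius * np.sqrt(rng.random(n))
    phi = rng.uniform(0, 2 * np.pi, n)
    x = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    f = rng.normal(0.0, np.sqrt(config.D_a / config.tau), size=(n, 2))
    return AOUPState(x=x, v=np.zeros((n, 2)), f=f, config=config)


def soft_core_force_mag(r: np.ndarray, R: float) -> np.ndarray:
    """|-dV/dr| for V = exp(-r^3/R^3): 3 r^2 exp(-r^3/R^3) / R^3."""
    r = np.asarray(r, dtype=float)
    return 3.0 * r**2 * np.exp(-(r**3) / R**3) / R**3


def aoup_pair_force(pos_i, pos_j, R: float) -> np.ndarray:
    """Force on particle i from j: -grad_i V(|x_i - x_j|).

    Repulsive (points from j toward i).  The r -> 0 limit is zero because
    the magnitude scales as r^2, so coincident particles exert no force.
    """
    d = np.asarray(pos_i, dtype=float) - np.asarray(pos_j, dtype=float)
    r = np.linalg.norm(d)
    if r == 0.0:
        return np.zeros_like(d)
    return soft_core_force_mag(r, R) * d / r


def pair_force_matrix(positions: np.ndarray, R: float) -> np.ndarray:
    """(n, n, 2) array: [i, j] = force on i from j (diagonal zero)."""
    d = positions[:, None, :] - positions[None, :, :]
    r = np.linalg.norm(d, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(r > 0.0, soft_core_force_mag(r, R) / r, 0.0)
    return coef[..., None] * d


try:  # pairwise-symmetric accumulation; NumPy fallback below
    import numba as _nb

    @_nb.njit(fastmath=True, cache=False, error_model="numpy")
    def _total_force_nb(pos, R):
        n = pos.shape[0]
        out = np.zeros((n, 2))
        R3 = R**3
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                r2 = dx * dx + dy * dy
                if r2 == 0.0:
                    continue
                r = np.sqrt(r2)
                coef = 3.0 * r * np.exp(-(r2 * r) / R3) / R3
                fx, fy = coef * dx, coef * dy
                out[i, 0] += fx
                out[i, 1] += fy
                out[j, 0] -= fx
                out[j, 1] -= fy
        return out

    _total_force_nb(np.zeros((2, 2)), 1.0)
except Exception:  # pragma: no cover - numba is optional
    _total_force_nb = None


def total_internal_force(positions: np.ndarray, R: float) -> np.ndarray:
    if _total_force_nb is not None:
        return _total_force_nb(np.ascontiguousarray(positions, dtype=float),
                               float(R))
    return pair_force_matrix(positions, R).sum(axis=1)


def ou_propulsion_step(f: np.ndarray, tau: float, D_a: float, dt: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Euler-Maruyama update of tau df/dt = -f + sqrt(2 D_a) w."""
    noise = rng.normal(0.0, 1.0, size=np.shape(f))
    return f - (dt / tau) * f + (np.sqrt(2.0 * D_a) / tau) * np.sqrt(dt) * noise


def aoup_step(state: AOUPState, rng: np.random.Generator) -> AOUPState:
    """One integration step: propulsion, then velocity, then position."""
    cfg = state.config
    f_new = ou_propulsion_step(state.f, cfg.tau, cfg.D_a, cfg.dt, rng)
    force = total_internal_force(state.x, cfg.R) - cfg.k * state.x
    thermal = (np.sqrt(2.0 * cfg.gamma * cfg.T) / cfg.gamma
               * np.sqrt(cfg.dt) * rng.normal(0.0, 1.0, size=state.x.shape))
    v_new = force / cfg.gamma * cfg.dt + thermal + f_new * cfg.dt
    return AOUPState(x=state.x + v_new, v=v_new, f=f_new, config=cfg)


def simulate(config: AOUPConfig, n_steps: int, rng: np.random.Generator,
             store_every: int = 1,
             init: AOUPState | None = None) -> tuple[np.ndarray, AOUPState]:
    """Run the dynamics; returns stored position snapshots and final state.

    positions: (n_stored, n, 2), including the initial configuration.
    """
    config = config.validate()
    state = init if init is not None else initial_state(rng, config)
    stored = [state.x.copy()]
    for step in range(1, n_steps + 1):
        state = aoup_step(state, rng)
        if step % store_every == 0:
            stored.append(state.x.copy())
    return np.asarray(stored), state
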