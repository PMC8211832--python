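"""Game-of-Life cellular automaton on a bounded grid.

Each cell is an agent with state (x, y, c): integer grid position and a
binary alive flag.  A live cell survives with two or three live Moore
neighbors; a dead cell becomes alive with exactly three.  The grid is
non-periodic, so edge cells have fewer than eight neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CAConfig:
    width: int = 14
    height: int = 14
    p_alive: float = 0.5

    def validate(self) -> "CAConfig":
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        if not 0.0 <= self.p_alive <= 1.0:
            raise ValueError("p_alive must lie in [0, 1]")
        return self


@dataclass
class CAGrid:
    """Binary alive/dead states on a width x height grid (row-major cells)."""

    state: np.ndarray  # (height, width) in {0, 1}
    config: CAConfig = field(default_factory=CAConfig)

    def __post_init__(self):
        self.state = np.asarray(self.state)
        if self.state.shape != (self.config.height, self.config.width):
            raise ValueError("state shape must be (height, width)")
        if not np.isin(self.state, (0, 1)).all():
            raise ValueError("cell states must be binary")
        self.state = self.state.astype(np.int8)

    @property
    def n_cells(self) -> int:
        return self.state.size

    def cell_xy(self, i: int) -> tuple[int, int]:
        """Row-major cell index -> (x, y) = (column, row)."""
        y, x = divmod(int(i), self.config.width)
        return x, y

    def as_states(self) -> np.ndarray:
        """Per-cell state rows (x, y, c), shape (n_cells, 3)."""
        h, w = self.state.shape
        ys, xs = np.mgrid[0:h, 0:w]
        return np.column_stack(
            [xs.ravel(), ys.ravel(), self.state.ravel()]
        ).astype(float)


def random_grid(rng: np.random.Generator, config: CAConfig | None = None) -> CAGrid:
    config = (config or CAConfig()).validate()
    state = (rng.random((config.height, config.width)) < config.p_alive)
    return CAGrid(state=state.astype(np.int8), config=config)


def neighbor_counts(state: np.ndarray) -> np.ndarray:
    """Live-neighbor counts on the 8-cell Moore neighborhood, zero-padded."""
    padded = np.pad(state.astype(np.int32), 1)
    h, w = state.shape
    counts = np.zeros((h, w), dtype=np.int32)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            counts += padded[1 + dy:1 + dy + h, 1 + dx:1 + dx + w]
    return counts


def ca_step(grid: CAGrid) -> CAGrid:
    """Advance one step; positions are static, only alive flags change."""
    if not np.isin(grid.state, (0, 1)).all():
        raise ValueError("cell states must be binary")
    h = neighbor_counts(grid.state)
    alive = grid.state == 1
    survive = alive & ((h == 2) | (h == 3))
    birth = (~alive) & (h == 3)
    return CAGrid(state=(survive | birth).astype(np.int8), config=grid.config)


def ca_interaction(grid: CAGrid, i: int, j: int) -> float:
    """Ground-truth interaction strength w^c: 1 for Moore neighbors, else 0.

    Membership uses Euclidean distance <= sqrt(2), i.e. Chebyshev distance 1.
    """
    if i == j:
        raise ValueError("self-interaction is not defined (i must differ from j)")
    xi, yi = grid.cell_xy(i)
    xj, yj = grid.cell_xy(j)
    return 1.0 if max(abs(xi - xj), abs(yi - yj)) <= 1 else 0.0


def neighbor_mask(config: CAConfig) -> np.ndarray:
    """(n_cells, n_cells) boolean ground-truth membership matrix (diag False)."""
    h, w = config.height, config.width
    ys, xs = np.mgrid[0:h, 0:w]
    xs, ys = xs.ravel(), ys.ravel()
    cheb = np.maximum(
        np.abs(xs[:, None] - xs[None, :]), np.abs(ys[:, None] - ys[None, :])
    )
    mask = cheb <= 1
    np.fill_diagonal(mask, False)
    return mask
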