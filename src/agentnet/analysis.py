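"""Diagnostics connecting trained models to ground truth.

Covers trajectory-error metrics (ADE/FDE), a constant-velocity
extrapolation baseline, the attention-versus-pair-force linear fit,
hexagonal lattice-spacing estimation from the pair-distance distribution,
interaction-sector recovery from heading-aligned attention maps, and
velocity-correlation heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

from .simulators import aoup as aoup_mod


# ----------------------------------------------------------------- ADE / FDE
def ade_fde(predicted: np.ndarray, true: np.ndarray,
            lengths: np.ndarray | None = None) -> tuple[float, float]:
    """Average and final displacement error between trajectory sets.

    predicted/true: (T, n, 2) or (B, T, n, 2).  ADE averages the Euclidean
    error over all steps and agents; FDE averages the error at each
    agent's final step (the last step, or `lengths[agent]-1` per agent
    when trajectories terminate early).
    """
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape:
        raise ValueError("predicted and true trajectories must share a shape")
    if p.ndim == 3:
        p, t = p[None], t[None]
    err = np.linalg.norm(p - t, axis=-1)       # (B, T, n)
    ade = float(err.mean())
    if lengths is None:
        fde = float(err[:, -1, :].mean())
    else:
        lengths = np.asarray(lengths, dtype=int)
        B, T, n = err.shape
        fde = float(err[:, lengths - 1, np.arange(n)].mean())
    return ade, fde


def linear_extrapolation(window: np.ndarray, n_steps: int) -> np.ndarray:
    """Constant-velocity continuation from the last observed velocity.

    window: (T_obs, n, 2) positions with T_obs >= 2; returns (n_steps, n, 2).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 3 or window.shape[0] < 2:
        raise ValueError("need at least two observed steps of (n, 2) positions")
    v = window[-1] - window[-2]
    steps = np.arange(1, n_steps + 1)[:, None, None]
    return window[-1][None] + steps * v[None]


# -------------------------------------------------------- attention-force fit
@dataclass
class FitResult:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if np.isfinite(self.r_squared):
            self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))


def linear_fit(x: np.ndarray, y: np.ndarray) -> FitResult:
    res = stats.linregress(np.asarray(x, float), np.asarray(y, float))
    return FitResult(res.slope, res.intercept, res.rvalue**2)


def attention_force_fit(alpha: np.ndarray, positions: np.ndarray,
                        R: float, component: int = 0) -> FitResult:
    """OLS of attention against the ground-truth pair-force magnitude.

    alpha: (n, n) attention for one velocity component (diagonal ignored);
    positions: (n, 2).  The regressor is |F_component| of the soft-core
    pair force exerted on i by j.
    """
    alpha = np.asarray(alpha, dtype=float)
    n = alpha.shape[0]
    forces = aoup_mod.pair_force_matrix(np.asarray(positions, float), R)
    off = ~np.eye(n, dtype=bool)
    return linear_fit(np.abs(forces[..., component][off]), alpha[off])


def attention_force_curve(alpha: np.ndarray, positions: np.ndarray,
                          R: float, component: int = 0):
    """(r_ij, |F|, scaled attention) tuples for the distance-profile plot.

    The attention scale factor c is fitted by least squares (attention ~ c
    * |F|) rather than assumed.
    """
    alpha = np.asarray(alpha, dtype=float)
    pos = np.asarray(positions, dtype=float)
    n = alpha.shape[0]
    d = pos[:, None] - pos[None, :]
    r = np.linalg.norm(d, axis=-1)
    forces = np.abs(aoup_mod.pair_force_matrix(pos, R)[..., component])
    off = ~np.eye(n, dtype=bool)
    fit = linear_fit(forces[off], alpha[off])
    c = fit.slope if fit.slope != 0 else 1.0
    return r[off], forces[off], alpha[off] / c, c


# ------------------------------------------------------- lattice periodicity
@dataclass
class PeriodicityResult:
    spacing: float
    confident: bool
    histogram: np.ndarray
    bin_edges: np.ndarray


def hexagonal_periodicity(positions: np.ndarray, R: float,
                          bin_width: float | None = None,
                          r_max: float | None = None,
                          min_r: float = 0.0,
                          min_prominence: float = 1.5) -> PeriodicityResult:
    """Lattice spacing from the first peak of the pair-distance histogram.

    positions: (n, 2) or (n_frames, n, 2) — frames are pooled.  Binning
    defaults to width R/20 on (0, 4R); the first local maximum at
    r >= `min_r` whose height exceeds `min_prominence` times the mean
    histogram level in that range is refined by quadratic interpolation
    around the modal bin.  If no such peak exists the result is flagged
    low-confidence and the global mode is reported.

    In a cluster crystal several particles share one lattice site, so the
    distance histogram has an intra-site peak near zero; pass
    `min_r ~ 0.7 R` to measure the inter-site lattice constant instead.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    bin_width = R / 20.0 if bin_width is None else bin_width
    r_max = 4.0 * R if r_max is None else r_max
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for frame in pos:
        d = pdist(frame)
        counts += np.histogram(d[d < r_max], bins=edges)[0]
    # normalize by the annulus area to approximate a radial distribution
    centers = 0.5 * (edges[:-1] + edges[1:])
    rdf = counts / np.maximum(centers, bin_width / 2)
    smooth = np.convolve(rdf, np.ones(3) / 3.0, mode="same")
    searchable = centers >= min_r
    in_range = smooth[searchable]
    level = in_range[in_range > 0].mean() if (in_range > 0).any() else 0.0
    start = int(np.argmax(searchable))
    peak = None
    for i in range(max(start, 1), len(rdf) - 1):
        if not (smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1]
                and smooth[i] > min_prominence * level):
            continue
        # Poisson significance: the smoothed excess over the mean level
        # must exceed 3 sigma of the windowed count noise
        window = counts[i - 1:i + 2].sum()
        sigma = np.sqrt(max(window, 1.0)) / (3.0 * centers[i])
        if window >= 10 and smooth[i] - level > 3.0 * sigma:
            # refine to the raw modal bin within the smoothed peak
            peak = i - 1 + int(np.argmax(rdf[i - 1:i + 2]))
            break
    confident = peak is not None
    if peak is None:
        peak = start + int(np.argmax(rdf[searchable]))
    # quadratic interpolation around the modal bin
    if 0 < peak < len(rdf) - 1:
        y0, y1, y2 = rdf[peak - 1], rdf[peak], rdf[peak + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    spacing = float(centers[peak] + shift * bin_width)
    return PeriodicityResult(spacing, confident, counts, edges)


# --------------------------------------------------------- attention maps
@dataclass
class AttentionMap:
    """Source points in the target's heading-aligned frame with attention.

    rel: (n_points, 2) relative positions rotated so the target heading
    lies along +x; alpha: (n_points, n_vars).
    """

    rel: np.ndarray
    alpha: np.ndarray
    var_names: tuple[str, ...] = ()


def _headings(velocities: np.ndarray) -> np.ndarray:
    return np.arctan2(velocities[..., 1], velocities[..., 0])


def heading_aligned_pairs(positions: np.ndarray, velocities: np.ndarray):
    """Relative source coordinates rotated into each target's heading frame.

    positions/velocities: (n, 2).  Returns (rel (n, n, 2), valid (n,))
    where valid flags targets with nonzero speed (zero-speed agents have
    no heading and are excluded from maps).
    """
    pos = np.asarray(positions, float)
    vel = np.asarray(velocities, float)
    d = pos[None, :, :] - pos[:, None, :]          # [i, j] = x_j - x_i
    theta = _headings(vel)
    cos, sin = np.cos(-theta), np.sin(-theta)
    rel = np.empty_like(d)
    rel[..., 0] = cos[:, None] * d[..., 0] - sin[:, None] * d[..., 1]
    rel[..., 1] = sin[:, None] * d[..., 0] + cos[:, None] * d[..., 1]
    valid = np.linalg.norm(vel, axis=-1) > 0
    return rel, valid


def attention_map(model, states: np.ndarray,
                  pos_idx=(0, 1), vel_idx=(2, 3)) -> AttentionMap:
    """Pool heading-aligned attention points over a batch of frames.

    states: (B, n, d) raw frames for a trained static model.  With
    `vel_idx=None` (e.g. grid systems without velocities) the relative
    coordinates are left unrotated.
    """
    states = np.asarray(states, dtype=float)
    if states.ndim == 2:
        states = states[None]
    rels, alphas = [], []
    for frame in states:
        res = model.forward(frame)
        alpha = res.alpha_full()                   # (n, n, Q)
        pos = frame[:, list(pos_idx)]
        if vel_idx is None:
            rel = pos[None, :, :] - pos[:, None, :]
            valid = np.ones(frame.shape[0], dtype=bool)
        else:
            rel, valid = heading_aligned_pairs(pos, frame[:, list(vel_idx)])
        n = frame.shape[0]
        off = ~np.eye(n, dtype=bool)
        keep = off & valid[:, None]
        rels.append(rel[keep])
        alphas.append(alpha[keep])
    return AttentionMap(np.concatenate(rels), np.concatenate(alphas))


def binned_map(rel: np.ndarray, values: np.ndarray, extent: float,
               n_bins: int = 40):
    """Mean of `values` on a square grid of relative coordinates.

    Empty bins are NaN.  Returns (grid (n_bins, n_bins), edges).
    """
    edges = np.linspace(-extent, extent, n_bins + 1)
    sums, _, _ = np.histogram2d(rel[:, 0], rel[:, 1], bins=[edges, edges],
                                weights=values)
    counts, _, _ = np.histogram2d(rel[:, 0], rel[:, 1], bins=[edges, edges])
    with np.errstate(invalid="ignore"):
        grid = sums / counts
    return grid, edges


# ---------------------------------------------------------- sector recovery
@dataclass
class SectorResult:
    radius: float
    angular_width_deg: float
    confident: bool


def sector_recovery(amap: AttentionMap, var: int = 0,
                    coverage: float = 0.95) -> SectorResult:
    """Estimate the interaction sector from a heading-aligned attention map.

    Points with attention above half its maximum are taken as the
    interaction region; the radius is the `coverage` quantile of their
    distances and the angular width is the central bearing interval
    holding `coverage` of the attention mass, debiased by 1/coverage so a
    uniform sector is estimated without shrinkage.
    """
    alpha = np.asarray(amap.alpha, dtype=float)
    if alpha.ndim == 2:
        alpha = alpha[:, var]
    if alpha.size == 0:
        return SectorResult(np.nan, np.nan, False)
    thr = 0.5 * alpha.max()
    sel = alpha >= thr
    if not sel.any() or alpha.max() <= 0:
        return SectorResult(np.nan, np.nan, False)
    rel = amap.rel[sel]
    w = alpha[sel]
    r = np.linalg.norm(rel, axis=-1)
    radius = float(np.quantile(r, coverage))
    bearing = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    lo = _weighted_quantile(bearing, w, (1 - coverage) / 2)
    hi = _weighted_quantile(bearing, w, 1 - (1 - coverage) / 2)
    width = min((hi - lo) / coverage, 360.0)
    return SectorResult(float(radius), float(width), True)


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(q, cum, x))


# ------------------------------------------------------ velocity correlation
def velocity_correlation_map(positions: np.ndarray, velocities: np.ndarray,
                             extent: float, n_bins: int = 40):
    """Mean pairwise velocity cosine similarity vs heading-aligned offset.

    positions/velocities: (n, 2) or (B, n, 2).  Empty bins are NaN.
    """
    pos = np.asarray(positions, float)
    vel = np.asarray(velocities, float)
    if pos.ndim == 2:
        pos, vel = pos[None], vel[None]
    rels, cosims = [], []
    for p, v in zip(pos, vel):
        rel, valid = heading_aligned_pairs(p, v)
        norms = np.linalg.norm(v, axis=-1)
        ok = valid[:, None] & (norms[None, :] > 0)
        n = p.shape[0]
        off = ~np.eye(n, dtype=bool)
        keep = off & ok
        dots = (v[:, None, :] * v[None, :, :]).sum(-1)
        cos = dots / np.maximum(norms[:, None] * norms[None, :], 1e-300)
        rels.append(rel[keep])
        cosims.append(cos[keep])
    return binned_map(np.concatenate(rels), np.concatenate(cosims),
                      extent, n_bins)
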