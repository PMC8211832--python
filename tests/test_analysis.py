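"""Analysis estimators on constructed inputs with known answers."""

import numpy as np
import pytest

from agentnet import analysis
from agentnet.analysis import (AttentionMap, ade_fde, attention_force_fit,
                               hexagonal_periodicity, linear_extrapolation,
                               sector_recovery, velocity_correlation_map)
from agentnet.simulators.aoup import pair_force_matrix


class TestAdeFde:
    def test_identical_trajectories_are_zero(self, rng):
        t = rng.normal(size=(5, 4, 2))
        assert ade_fde(t, t) == (0.0, 0.0)

    def test_constant_offset(self, rng):
        t = rng.normal(size=(5, 4, 2))
        ade, fde = ade_fde(t + np.array([3.0, 4.0]), t)
        assert np.isclose(ade, 5.0) and np.isclose(fde, 5.0)

    def test_two_step_hand_example(self):
        true = np.zeros((2, 1, 2))
        pred = np.array([[[0.3, 0.0]], [[0.5, 0.0]]])
        ade, fde = ade_fde(pred, true)
        assert np.isclose(ade, 0.4) and np.isclose(fde, 0.5)

    def test_rigid_motion_invariance(self, rng):
        p = rng.normal(size=(6, 3, 2))
        t = rng.normal(size=(6, 3, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        shift = np.array([2.0, -1.0])
        a1 = ade_fde(p, t)
        a2 = ade_fde(p @ rot.T + shift, t @ rot.T + shift)
        assert np.allclose(a1, a2)

    def test_per_agent_termination_steps(self):
        true = np.zeros((3, 2, 2))
        pred = np.zeros((3, 2, 2))
        pred[1, 0, 0] = 1.0   # agent 0 ends at step 1 with error 1
        pred[2, 1, 0] = 2.0   # agent 1 ends at step 2 with error 2
        _, fde = ade_fde(pred, true, lengths=np.array([2, 3]))
        assert np.isclose(fde, 1.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ade_fde(np.zeros((3, 2, 2)), np.zeros((4, 2, 2)))


class TestLinearExtrapolation:
    def test_stationary_agent_stays(self):
        w = np.zeros((3, 2, 2))
        pred = linear_extrapolation(w, 4)
        assert np.array_equal(pred, np.zeros((4, 2, 2)))

    def test_constant_velocity_is_exact(self):
        steps = np.arange(5)[:, None, None]
        v = np.array([[1.0, -0.5]])[None]
        truth = steps * v
        pred = linear_extrapolation(truth[:3], 2)
        assert np.allclose(pred, truth[3:])
        assert ade_fde(pred, truth[3:]) == (0.0, 0.0)

    def test_circular_motion_error_grows(self):
        t = np.linspace(0, np.pi, 30)
        traj = np.stack([np.cos(t), np.sin(t)], axis=-1)[:, None, :]
        pred = linear_extrapolation(traj[:10], 15)
        err = np.linalg.norm(pred - traj[10:25], axis=-1).ravel()
        assert err[-1] > err[0] > 0

    def test_single_step_window_rejected(self):
        with pytest.raises(ValueError):
            linear_extrapolation(np.zeros((1, 2, 2)), 3)


class TestForceFit:
    def test_attention_proportional_to_force_gives_r2_one(self, rng):
        pos = rng.normal(size=(12, 2)) * 2
        R = 2.0
        force = np.abs(pair_force_matrix(pos, R)[..., 0])
        alpha = 0.28 * force
        fit = attention_force_fit(alpha, pos, R, component=0)
        assert fit.r_squared > 0.999
        assert np.isclose(fit.slope, 0.28, rtol=1e-6)

    def test_noise_attention_gives_r2_near_zero(self, rng):
        pos = rng.normal(size=(12, 2)) * 2
        alpha = rng.random((12, 12))
        fit = attention_force_fit(alpha, pos, 2.0, component=0)
        assert fit.r_squared < 0.2

    def test_curve_returns_fitted_scale(self, rng):
        pos = rng.normal(size=(10, 2)) * 2
        force = np.abs(pair_force_matrix(pos, 2.0)[..., 0])
        r, f, scaled, c = analysis.attention_force_curve(
            0.5 * force, pos, 2.0, component=0)
        assert np.isclose(c, 0.5, rtol=1e-6)
        assert np.allclose(scaled, f, atol=1e-9)


def triangular_lattice(a: float, n_side: int = 8) -> np.ndarray:
    basis = np.array([[a, 0.0], [a / 2, a * np.sqrt(3) / 2]])
    pts = [i * basis[0] + j * basis[1]
           for i in range(n_side) for j in range(n_side)]
    return np.asarray(pts)


class TestPeriodicity:
    def test_perfect_lattice_recovered_within_bin(self):
        a, R = 2.8, 2.0
        est = hexagonal_periodicity(triangular_lattice(a), R)
        assert est.confident
        assert abs(est.spacing - a) <= R / 20

    def test_jittered_lattice_within_five_percent(self, rng):
        a, R = 2.8, 2.0
        pts = triangular_lattice(a) + rng.normal(0, 0.05 * a, size=(64, 2))
        est = hexagonal_periodicity(pts, R)
        assert est.confident
        assert abs(est.spacing - a) / a < 0.05

    def test_uniform_gas_flagged_low_confidence(self, rng):
        pts = rng.uniform(0, 50, size=(200, 2))
        est = hexagonal_periodicity(pts, R=1.0)
        assert not est.confident

    def test_scale_equivariance(self):
        a, R, lam = 2.8, 2.0, 3.0
        e1 = hexagonal_periodicity(triangular_lattice(a), R)
        e2 = hexagonal_periodicity(triangular_lattice(a * lam), R * lam)
        assert abs(e2.spacing - lam * e1.spacing) <= lam * R / 20

    def test_min_r_skips_intra_cluster_peak(self, rng):
        # two particles per site: near-zero distances must be ignored
        a, R = 2.8, 2.0
        lat = triangular_lattice(a)
        doubled = np.concatenate([lat, lat + rng.normal(0, 0.03, lat.shape)])
        est = hexagonal_periodicity(doubled, R, min_r=0.7 * R)
        assert abs(est.spacing - a) <= R / 10


def synthetic_sector_map(rng, radius=1.0, half_angle=60.0, n=4000,
                         extent=2.5):
    rel = rng.uniform(-extent, extent, size=(n, 2))
    r = np.linalg.norm(rel, axis=1)
    bearing = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    inside = (r < radius) & (np.abs(bearing) < half_angle)
    alpha = np.where(inside, 1.0, 1e-4)
    return AttentionMap(rel=rel, alpha=alpha[:, None])


class TestSectorRecovery:
    def test_sharp_sector_recovered(self, rng):
        amap = synthetic_sector_map(rng)
        sec = sector_recovery(amap)
        assert sec.confident
        assert abs(sec.radius - 1.0) < 0.05
        assert abs(sec.angular_width_deg - 120.0) < 10.0

    def test_full_disk_width_near_360(self, rng):
        amap = synthetic_sector_map(rng, half_angle=180.0)
        sec = sector_recovery(amap)
        assert sec.angular_width_deg > 345.0

    def test_all_zero_map_flagged(self):
        amap = AttentionMap(rel=np.zeros((10, 2)), alpha=np.zeros((10, 1)))
        sec = sector_recovery(amap)
        assert not sec.confident


class TestVelocityCorrelation:
    def test_shared_velocity_gives_unity(self, rng):
        pos = rng.normal(size=(30, 2))
        vel = np.tile([1.0, 0.5], (30, 1))
        grid, _ = velocity_correlation_map(pos, vel, extent=3.0, n_bins=10)
        vals = grid[np.isfinite(grid)]
        assert np.allclose(vals, 1.0)

    def test_random_velocities_average_near_zero(self, rng):
        pos = rng.normal(size=(40, 2)) * 2
        vel = rng.normal(size=(30, 40, 2))
        grids = [velocity_correlation_map(pos, v, extent=4.0, n_bins=6)[0]
                 for v in vel]
        pooled = np.nanmean(np.stack(grids), axis=0)
        assert np.nanmax(np.abs(pooled)) < 0.35


def test_flock_has_positive_short_range_velocity_correlation():
    from agentnet.simulators import vicsek
    from agentnet.utils import rng_from

    cfg = vicsek.VicsekConfig(n_agents=60, sigma=0.05)
    rng = rng_from(11, "flock")
    states = vicsek.simulate(cfg, 15, rng)
    pos = np.stack([s.x for s in states[10:]])
    vel = np.stack([s.v for s in states[10:]])
    grid, edges = velocity_correlation_map(pos, vel, extent=2.0, n_bins=8)
    centers = 0.5 * (edges[:-1] + edges[1:])
    xx, yy = np.meshgrid(centers, centers, indexing="ij")
    near = (np.hypot(xx, yy) < 1.0) & np.isfinite(grid)
    assert np.nanmean(grid[near]) > 0.3


def test_binned_constant_field_is_constant(rng):
    rel = rng.uniform(-2, 2, size=(500, 2))
    grid, _ = analysis.binned_map(rel, np.full(500, 0.7), extent=2.0,
                                  n_bins=5)
    assert np.allclose(grid[np.isfinite(grid)], 0.7)
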