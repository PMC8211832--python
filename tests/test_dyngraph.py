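"""Dynamic-node registry: chains survive agents entering and leaving."""

import numpy as np
import pytest

from agentnet.data import TrajectoryBatch
from agentnet.dyngraph import (DynGraphRunner, OcclusionConfig, init_hidden,
                               sequence_nll, step_registry, synth_occlusion)
from agentnet.model import ModelConfig, Normalization, RecurrentAgentNet
from agentnet.nn.autodiff import Tensor


@pytest.fixture()
def model():
    cfg = ModelConfig.for_system("aoup", n_globals=0, att_mlp=(32, 16, 8, 1))
    m = RecurrentAgentNet(cfg, seed=3)
    m.set_normalization(Normalization.identity(4))
    return m


@pytest.fixture()
def states(rng):
    return rng.normal(size=(5, 6, 4))  # (T, N, d)


def test_init_hidden_dimensions(model):
    h, c = init_hidden(model, np.zeros((3, 4)))
    assert h.shape == (1, 3, 128) and c.shape == (1, 3, 128)


def test_identical_entering_states_get_identical_hiddens(model):
    h, c = init_hidden(model, np.array([[1.0, 2.0, 0.0, 1.0],
                                        [1.0, 2.0, 0.0, 1.0]]))
    assert np.array_equal(h.data[0, 0], h.data[0, 1])
    assert np.array_equal(c.data[0, 0], c.data[0, 1])


def test_reinitializing_present_agent_rejected(model, states):
    runner = DynGraphRunner(model)
    runner.step(states[0], np.ones(6, bool))
    with pytest.raises(ValueError, match="present"):
        init_hidden(model, states[0][:1], registry=runner.registry,
                    agent_ids=[0], step=0)


def test_static_case_equals_plain_recurrent_forward(model, states):
    plain = model.forward_window(states)
    runner = DynGraphRunner(model)
    for t in range(states.shape[0]):
        dyn = runner.step(states[t], np.ones(6, bool))
    assert np.array_equal(plain.mu.data, dyn.mu.data)
    assert np.array_equal(plain.var.data, dyn.var.data)
    for a_plain, a_dyn in zip(plain.alpha, dyn.alpha):
        assert np.array_equal(a_plain.data, a_dyn.data)


def test_absent_agent_contributes_no_attention(model, states):
    runner = DynGraphRunner(model)
    present = np.ones(6, bool)
    present[2] = False
    res = runner.step(states[0], present)
    assert res.mu.shape[1] == 5          # only present agents predicted
    assert res.attention().shape == (1, 5, 4, 4)
    assert list(res.agent_ids) == [0, 1, 3, 4, 5]


def test_new_agent_starts_fresh_chain(model, states):
    runner = DynGraphRunner(model)
    present0 = np.ones(6, bool)
    present0[5] = False
    runner.step(states[0], present0)
    assert 5 not in runner.registry
    runner.step(states[1], np.ones(6, bool))
    assert 5 in runner.registry
    assert runner.registry.get(5).last_seen == 1


def test_reappearing_agent_resumes_or_restarts(model, states):
    masks = np.ones((3, 6), bool)
    masks[1, 0] = False  # agent 0 absent in the middle
    outs = {}
    for resume in (True, False):
        runner = DynGraphRunner(model, resume_on_reappear=resume)
        for t in range(3):
            res = runner.step(states[t], masks[t])
        outs[resume] = res.mu.data.copy()
    assert not np.array_equal(outs[True], outs[False])


def test_loss_unchanged_by_always_absent_agent(model, states):
    present = np.ones(states.shape[:2], bool)
    base = float(sequence_nll(model, states, present).data)
    padded = np.concatenate([states, np.zeros((5, 1, 4))], axis=1)
    present_pad = np.concatenate([present, np.zeros((5, 1), bool)], axis=1)
    with_ghost = float(sequence_nll(model, padded, present_pad).data)
    assert base == with_ghost


def test_gradients_flow_into_init_mlps(model, states):
    model.zero_grad()
    loss = sequence_nll(model, states, np.ones(states.shape[:2], bool))
    loss.backward()
    grads = [p.grad for p in model.init_h.parameters()]
    assert all(g is not None for g in grads)
    assert any(np.abs(g).max() > 0 for g in grads)


def test_step_registry_functional_wrapper(model, states):
    runner = DynGraphRunner(model)
    registry, res = step_registry(model, runner, states[0], np.ones(6, bool))
    assert len(registry) == 6 and res.mu.shape == (1, 6, 4)


def test_weighted_sequence_loss_runs(model, states):
    present = np.ones(states.shape[:2], bool)
    present[3:, 4] = False  # one short trajectory
    val = sequence_nll(model, states, present, weight_by_length=True)
    assert np.isfinite(float(val.data))


class TestOcclusion:
    def batch(self, rng, S=4, T=20, N=10):
        return TrajectoryBatch(states=rng.normal(size=(S, T, N, 4)),
                               var_names=("x", "y", "v_x", "v_y"))

    def test_zero_rate_keeps_everyone_present(self, rng):
        masked = synth_occlusion(self.batch(rng), OcclusionConfig(rate=0.0),
                                 seed=1)
        assert masked.present.all()

    def test_median_presence_length_matches_target(self, rng):
        cfg = OcclusionConfig(median_length=6)
        masked = synth_occlusion(self.batch(rng, S=60), cfg, seed=2)
        lengths = masked.present.sum(axis=1).ravel()
        assert 4 <= np.median(lengths) <= 8

    def test_masks_reproducible_and_contiguous(self, rng):
        batch = self.batch(rng)
        a = synth_occlusion(batch, OcclusionConfig(median_length=5), seed=7)
        b = synth_occlusion(batch, OcclusionConfig(median_length=5), seed=7)
        assert np.array_equal(a.present, b.present)
        for s in range(a.present.shape[0]):
            for agent in range(a.present.shape[2]):
                on = np.flatnonzero(a.present[s, :, agent])
                if on.size:
                    assert np.array_equal(on, np.arange(on[0], on[-1] + 1))

    def test_non_contiguous_mode_punches_holes(self, rng):
        cfg = OcclusionConfig(median_length=15, contiguous=False)
        masked = synth_occlusion(self.batch(rng, S=30), cfg, seed=3)
        holes = 0
        for s in range(masked.present.shape[0]):
            for agent in range(masked.present.shape[2]):
                on = np.flatnonzero(masked.present[s, :, agent])
                if on.size and not np.array_equal(
                        on, np.arange(on[0], on[-1] + 1)):
                    holes += 1
        assert holes > 0
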