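"""Model contracts: interchangeability, equivariance, variable separation."""

import numpy as np
import pytest

from agentnet.model import (AgentNet, GAT3Baseline, GATBaseline, LSTMBaseline,
                            MLPBaseline, ModelConfig, RecurrentAgentNet)


@pytest.fixture(scope="module")
def vm_model():
    return AgentNet(ModelConfig.for_system("vicsek"), seed=1)


@pytest.fixture(scope="module")
def frames(rng_module):
    return rng_module.normal(size=(2, 7, 4))


@pytest.fixture(scope="module")
def rng_module():
    return np.random.default_rng(99)


def test_table_presets_validate():
    ca = ModelConfig.for_system("ca")
    assert (ca.input_dims, ca.n_out_vars, ca.att_dims) == (3, 1, 16)
    assert ca.att_mlp == (32, 32, 16, 1)
    vm = ModelConfig.for_system("vicsek")
    assert vm.att_mlp == (32, 64, 32, 1) and vm.n_out_vars == 2
    aoup = ModelConfig.for_system("aoup")
    # attention input width 2*16 + 1 global (R) = 33
    assert aoup.att_mlp[0] == 33 and aoup.n_globals == 1
    swift = ModelConfig.for_system("swift")
    assert swift.att_dims == 96 and swift.input_dims == 7
    with pytest.raises(ValueError):
        ModelConfig.for_system("aoup", n_globals=0)  # width no longer matches


def test_identical_states_get_identical_predictions(vm_model):
    x = np.array([[0.0, 0.0, 1.0, 0.0],
                  [2.0, 1.0, 0.0, 1.0],
                  [2.0, 1.0, 0.0, 1.0]])  # agents 1 and 2 interchangeable
    res = vm_model.forward(x)
    assert np.allclose(res.mu.data[0, 1], res.mu.data[0, 2], atol=1e-10)
    assert np.allclose(res.var.data[0, 1], res.var.data[0, 2], atol=1e-10)


def test_attention_bounds_and_shape(vm_model, frames):
    res = vm_model.forward(frames)
    att = res.attention()
    assert att.shape == (2, 7, 6, 2)
    assert np.all(att > 0.0) and np.all(att < 1.0)


def test_attention_is_asymmetric_in_general(vm_model, frames):
    alpha = vm_model.forward(frames).alpha_full()[0, :, :, 0]
    assert not np.allclose(alpha, alpha.T)


def test_permutation_equivariance(vm_model, frames, rng_module):
    perm = rng_module.permutation(frames.shape[1])
    res = vm_model.forward(frames)
    res_p = vm_model.forward(frames[:, perm])
    assert np.allclose(res_p.mu.data, res.mu.data[:, perm], atol=1e-12)
    alpha = res.alpha_full()
    alpha_p = res_p.alpha_full()
    assert np.allclose(alpha_p, alpha[:, perm][:, :, perm], atol=1e-12)


def test_variable_separation_attention_only_affects_own_variable(
        vm_model, frames):
    base = vm_model.forward(frames, att_bias=np.zeros(2))
    bumped = vm_model.forward(frames, att_bias=np.array([0.0, 0.7]))
    # perturbing attention of variable 1 leaves variable 0 untouched
    assert np.array_equal(base.mu.data[..., 0], bumped.mu.data[..., 0])
    assert np.array_equal(base.var.data[..., 0], bumped.var.data[..., 0])
    assert not np.allclose(base.mu.data[..., 1], bumped.mu.data[..., 1])


def test_attention_saturation_reduces_to_self_pathway(vm_model, rng_module):
    # alpha -> 0: predictions become independent of the other agents
    self_state = np.array([0.3, -0.2, 0.8, 0.1])
    a = np.vstack([self_state, rng_module.normal(size=(5, 4))])
    b = np.vstack([self_state, rng_module.normal(size=(5, 4))])
    ra = vm_model.forward(a, att_bias=np.full(2, -80.0))
    rb = vm_model.forward(b, att_bias=np.full(2, -80.0))
    assert np.allclose(ra.mu.data[0, 0], rb.mu.data[0, 0], atol=1e-12)


def test_single_agent_frame(vm_model):
    res = vm_model.forward(np.array([[0.0, 0.0, 1.0, 0.0]]))
    assert res.mu.shape == (1, 1, 2)
    assert res.attention().shape == (1, 0, 2)  # no sources for one agent


def test_nan_input_rejected(vm_model):
    bad = np.full((3, 4), np.nan)
    with pytest.raises(ValueError, match="NaN|finite"):
        vm_model.forward(bad)
    with pytest.raises(ValueError, match="agents"):
        vm_model.forward(np.zeros((3, 5)))


def test_variance_strictly_positive(vm_model, frames):
    res = vm_model.forward(frames)
    assert np.all(res.var.data > 0.0)
    assert res.variance().shape == (2, 7, 2)


def test_dedupe_path_matches_full_attention():
    from agentnet.simulators.datasets import generate_ca
    from agentnet.simulators.ca import CAConfig

    ds = generate_ca(CAConfig(), 3, seed=8)
    dedup = AgentNet(ModelConfig.for_system("ca"), seed=4)
    full = AgentNet(ModelConfig.for_system("ca", dedupe_pairs=False), seed=4)
    r1, r2 = dedup.forward(ds.inputs), full.forward(ds.inputs)
    assert np.array_equal(r1.logits.data, r2.logits.data)
    assert np.array_equal(r1.alpha_full(), r2.alpha_full())


def test_aoup_model_requires_global_variable(rng_module):
    model = RecurrentAgentNet(ModelConfig.for_system("aoup"), seed=0)
    window = rng_module.normal(size=(2, 3, 5, 4))
    with pytest.raises(ValueError, match="global"):
        model.forward_window(window)
    res = model.forward_window(window, globals_=np.array([[3.0], [2.5]]))
    assert res.mu.shape == (2, 5, 4)
    assert res.attention().shape == (2, 5, 4, 4)


def test_recurrent_model_uses_history(rng_module):
    cfg = ModelConfig.for_system("aoup", n_globals=0, att_mlp=(32, 16, 8, 1))
    model = RecurrentAgentNet(cfg, seed=0)
    w1 = rng_module.normal(size=(4, 5, 4))
    w2 = w1.copy()
    w2[0] += 1.0  # change only the oldest observation
    r1 = model.forward_window(w1)
    r2 = model.forward_window(w2)
    assert not np.allclose(r1.mu.data, r2.mu.data)


def test_shared_decoder_variant(frames):
    """The single-decoder layout runs with the same I/O contract but
    mixes contexts, so variable separation no longer holds."""
    cfg = ModelConfig.for_system("vicsek", per_variable_decoder=False)
    model = AgentNet(cfg, seed=3)
    res = model.forward(frames)
    assert res.mu.shape == (2, 7, 2) and res.var.shape == (2, 7, 2)
    base = model.forward(frames, att_bias=np.zeros(2))
    bumped = model.forward(frames, att_bias=np.array([0.0, 0.7]))
    assert not np.allclose(base.mu.data[..., 0], bumped.mu.data[..., 0])


class TestBaselines:
    cfg = ModelConfig.for_system("vicsek")

    def test_gat_returns_single_attention_per_pair(self, frames):
        model = GATBaseline(self.cfg, seed=2)
        res = model.forward(frames)
        assert len(res.alpha) == 1
        w = res.alpha[0].data
        # softmax normalization over sources
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        assert res.mu.shape == (2, 7, 2)

    def test_gat3_has_three_heads(self, frames):
        model = GAT3Baseline(self.cfg, seed=2, head_dim=12)
        res = model.forward(frames)
        assert model.n_heads == 3 and len(res.alpha) == 3

    def test_mlp_baseline_ignores_other_agents(self, rng_module):
        model = MLPBaseline(self.cfg, seed=2)
        a = rng_module.normal(size=(1, 6, 4))
        b = a.copy()
        b[0, 1:] += rng_module.normal(size=(5, 4))  # perturb everyone else
        ra, rb = model.forward(a), model.forward(b)
        assert np.array_equal(ra.mu.data[0, 0], rb.mu.data[0, 0])

    def test_lstm_baseline_ignores_other_agents(self, rng_module):
        cfg = ModelConfig.for_system("aoup", n_globals=0,
                                     att_mlp=(32, 16, 8, 1))
        model = LSTMBaseline(cfg, seed=2)
        a = rng_module.normal(size=(3, 6, 4))
        b = a.copy()
        b[:, 1:] += 1.0
        ra, rb = model.forward_window(a), model.forward_window(b)
        assert np.array_equal(ra.mu.data[0, 0], rb.mu.data[0, 0])
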