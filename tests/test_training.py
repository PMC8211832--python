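"""Loss closed forms, schedule behavior, rollout contracts."""

import numpy as np
import pytest

from agentnet.model import AgentNet, ModelConfig, RecurrentAgentNet
from agentnet.nn.autodiff import Tensor
from agentnet.simulators.aoup import AOUPConfig
from agentnet.simulators.ca import CAConfig
from agentnet.simulators.datasets import (generate_aoup, generate_ca,
                                          generate_vicsek)
from agentnet.simulators.vicsek import VicsekConfig
from agentnet.training import (TrainConfig, TrainingDiverged, ca_accuracy,
                               length_weights, loss_bce, loss_nll_gaussian,
                               loss_weighted_nll, rollout, train)


class TestBCE:
    def test_perfect_prediction_is_zero(self):
        labels = np.array([0.0, 1.0, 1.0])
        assert float(loss_bce(labels, labels).data) < 1e-5

    def test_uniform_prediction_is_ln2(self):
        p = np.full(10, 0.5)
        labels = (np.arange(10) % 2).astype(float)
        assert np.isclose(float(loss_bce(p, labels).data), np.log(2.0))

    def test_confident_correct_prediction(self):
        val = float(loss_bce(np.array([0.9]), np.array([1.0])).data)
        assert np.isclose(val, -np.log(0.9), atol=1e-9)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            loss_bce(np.array([0.5]), np.array([0.3]))


class TestGaussianNLL:
    def test_zero_at_matching_mean_and_special_variance(self):
        s2 = 1.0 / (2 * np.pi)
        val = loss_nll_gaussian(np.zeros((1, 1)), np.full((1, 1), s2),
                                np.zeros((1, 1)))
        assert abs(float(val.data)) < 1e-12

    def test_standard_normal_at_mean(self):
        val = loss_nll_gaussian(np.zeros((1, 1)), np.ones((1, 1)),
                                np.zeros((1, 1)))
        assert np.isclose(float(val.data), 0.5 * np.log(2 * np.pi))

    def test_gradient_pushes_variance_up_for_large_errors(self):
        var = Tensor(np.array([[1.0]]), requires_grad=True)
        loss = loss_nll_gaussian(Tensor(np.array([[0.0]])), var,
                                 np.array([[5.0]]))
        loss.backward()
        assert var.grad[0, 0] < 0  # increasing variance lowers the loss

    def test_sums_variables_means_agents(self):
        mu = np.zeros((4, 3))
        var = np.ones((4, 3))
        val = float(loss_nll_gaussian(mu, var, np.zeros((4, 3))).data)
        assert np.isclose(val, 3 * 0.5 * np.log(2 * np.pi))


class TestWeightedNLL:
    def test_uniform_lengths_match_unweighted(self, rng):
        nll = rng.normal(size=(6, 5)) ** 2
        lengths = np.full(6, 5)
        weighted = float(loss_weighted_nll(nll, lengths).data)
        assert np.isclose(weighted, nll.mean())

    def test_inverse_frequency_ratio(self):
        lengths = np.array([4, 4, 4, 8])  # 3:1 frequency -> 1:3 weights
        w = length_weights(lengths)
        assert np.isclose(w[3] / w[0], 3.0)
        assert np.isclose((w * lengths).sum(), lengths.sum())

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty|batch"):
            loss_weighted_nll(np.zeros((0, 4)), np.zeros(0, dtype=int))


def test_training_reduces_loss_and_is_reproducible():
    ds = generate_ca(CAConfig(width=8, height=8), 24, seed=3)
    logs = []
    for _ in range(2):
        model = AgentNet(ModelConfig.for_system(
            "ca", input_dims=3, dedupe_pairs=True), seed=5)
        log = train(model, ds, TrainConfig(epochs=3, batch_size=8, seed=2,
                                           lr=2e-3, test_fraction=0.25))
        logs.append(log.column("train_loss"))
    assert logs[0][-1] < logs[0][0]
    assert np.array_equal(logs[0], logs[1])


def test_divergence_raises():
    ds = generate_ca(CAConfig(width=6, height=6), 8, seed=3)
    model = AgentNet(ModelConfig.for_system("ca"), seed=5)
    model.parameters()[0].data[0, 0] = np.inf
    with pytest.raises(TrainingDiverged):
        train(model, ds, TrainConfig(epochs=1, batch_size=4, seed=0))


def test_vicsek_training_smoke():
    ds = generate_vicsek(VicsekConfig(n_agents=8), 24, seed=3)
    model = AgentNet(ModelConfig.for_system("vicsek"), seed=5)
    log = train(model, ds, TrainConfig(epochs=3, batch_size=8, seed=2, lr=2e-3))
    assert log.column("train_loss")[-1] < log.column("train_loss")[0]


@pytest.fixture(scope="module")
def trained():
    ds = generate_aoup(AOUPConfig(n_particles=5), 8, seed=6, burn_in=20)
    model = RecurrentAgentNet(ModelConfig.for_system("aoup"), seed=1)
    train(model, ds, TrainConfig(epochs=2, batch_size=4, seed=0,
                                 test_fraction=0.25))
    return model, ds


class TestRollout:

    def test_zero_steps_yields_empty_prediction(self, trained):
        model, ds = trained
        out, attn = rollout(model, ds.inputs[0], 0, seed=1,
                            globals_=ds.R[:1, None])
        assert out.shape == (0, 5, 4) and attn == []

    def test_long_rollout_supported(self, trained):
        model, ds = trained
        out, attn = rollout(model, ds.inputs[:2], 42, seed=1,
                            globals_=ds.R[:2, None])
        assert out.shape == (2, 42, 5, 4)
        assert len(attn) == 42
        assert attn[0].shape == (2, 5, 4, 4)
        assert np.isfinite(out).all()

    def test_degenerate_variance_recovers_mean_rollout(self, trained):
        model, ds = trained
        # drive all variance heads to (near) zero output
        for head in model.core.var_heads:
            head.layers[-1].bias.data[...] = -40.0
            head.layers[-1].weight.data[...] = 0.0
        sampled, _ = rollout(model, ds.inputs[0], 2, seed=3,
                             globals_=ds.R[:1, None])
        mean, _ = rollout(model, ds.inputs[0], 2, seed=4,
                          globals_=ds.R[:1, None], sample_mode="mean")
        assert np.allclose(sampled, mean, atol=1e-2)

    def test_rollout_requires_full_state_prediction(self):
        model = AgentNet(ModelConfig.for_system("vicsek"), seed=0)
        model.cfg = ModelConfig.for_system("vicsek")
        with pytest.raises(ValueError, match="full state"):
            rollout(model, np.zeros((3, 4, 4)), 2)


def test_gradcheck_losses_through_tiny_model(rng):
    """End-to-end gradient of BCE and NLL losses vs finite differences."""
    from agentnet.training import _static_batch_loss
    from agentnet.model import Normalization

    ca_model = AgentNet(ModelConfig.for_system(
        "ca", att_dims=4, att_mlp=(8, 6, 1), encoder_hidden=8,
        decoder_hidden=6, head_hidden=4, dedupe_pairs=False), seed=2)
    ca_model.set_normalization(Normalization.identity(3))
    x = rng.normal(size=(2, 4, 3))
    y = (rng.random((2, 4)) < 0.5).astype(float)

    def check(model, inputs, targets):
        model.zero_grad()
        loss, _ = _static_batch_loss(model, inputs, targets)
        loss.backward()
        for p in model.parameters()[:3]:
            flat = p.data.reshape(-1)
            i = 0
            eps = 1e-6
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(_static_batch_loss(model, inputs, targets)[0].data)
            flat[i] = orig - eps
            lo = float(_static_batch_loss(model, inputs, targets)[0].data)
            flat[i] = orig
            num = (hi - lo) / (2 * eps)
            ana = p.grad.reshape(-1)[i]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num))

    check(ca_model, x, y)

    vm_model = AgentNet(ModelConfig.for_system(
        "vicsek", att_dims=4, att_mlp=(8, 6, 1), encoder_hidden=8,
        decoder_hidden=6, head_hidden=4), seed=2)
    vm_model.set_normalization(Normalization.identity(4))
    xv = rng.normal(size=(2, 4, 4))
    tv = rng.normal(size=(2, 4, 2))
    check(vm_model, xv, tv)
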