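"""Losses, optimization schedule and rollout logic.

Training defaults: Adam (initial learning rate
0.0005), batch size 32, learning rate multiplied by 0.7 whenever the test
loss fails to improve by more than 1e-4 for a patience window (30 epochs
at full scale).  Binary systems train with binary cross-entropy;
stochastic systems with the sum over variables of univariate Gaussian
negative log-likelihoods.  Multi-step (recurrent) training feeds sampled
predictions back into the encoder via the reparameterization trick, so
gradients flow through the whole rollout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AgentNet, Normalization, RecurrentAgentNet
from .nn import Adam, ReduceLROnPlateau
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .simulators.datasets import AOUPDataset, CADataset, VicsekDataset
from .utils import rng_from

_BCE_EPS = 1e-7


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainConfig:
    lr: float = 5e-4
    decay_factor: float = 0.7
    plateau_patience: int = 30
    plateau_threshold: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    test_fraction: float = 0.1
    max_eval_samples: int = 96      # cap per-epoch test-loss evaluation
    teacher_forcing: bool = False   # multi-step: feed truth instead of samples

    def validate(self) -> "TrainConfig":
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 < self.decay_factor < 1.0:
            raise ValueError("decay_factor must lie in (0, 1)")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size and epochs must be positive")
        return self


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)

    def append(self, **kw):
        self.epochs.append(kw)

    def column(self, key: str) -> np.ndarray:
        return np.array([e[key] for e in self.epochs])


# ---------------------------------------------------------------------- losses
def _as_t(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def loss_bce(probabilities, labels) -> Tensor:
    """Mean binary cross-entropy between alive probabilities and labels."""
    labels = np.asarray(labels, dtype=float)
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    p = ad.clip(_as_t(probabilities), _BCE_EPS, 1.0 - _BCE_EPS)
    y = Tensor(labels)
    nll = -(y * ad.log(p) + (1.0 - y) * ad.log(1.0 - p))
    return nll.mean()


def loss_bce_logits(logits, labels) -> Tensor:
    """Numerically stable BCE on raw logits (used by the training loop)."""
    labels = np.asarray(labels, dtype=float)
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    z = _as_t(logits)
    return (ad.softplus(z) - Tensor(labels.astype(z.dtype)) * z).mean()


def loss_nll_gaussian(mu, var, target) -> Tensor:
    """Sum over variables, mean over agents of univariate Gaussian NLL."""
    mu, var = _as_t(mu), _as_t(var)
    x = Tensor(np.asarray(target, dtype=mu.dtype))
    nll = 0.5 * ad.log(2.0 * np.pi * var) + ad.square(x - mu) / (2.0 * var)
    return nll.sum(axis=-1).mean()


def length_weights(lengths: np.ndarray) -> np.ndarray:
    """Per-sample weights inversely proportional to the frequency of each
    trajectory-length class, scaled so the weighted step count matches the
    raw step count (all-equal lengths => all weights 1)."""
    lengths = np.asarray(lengths)
    if lengths.size == 0:
        raise ValueError("empty batch")
    classes, counts = np.unique(lengths, return_counts=True)
    freq = dict(zip(classes.tolist(), counts.tolist()))
    w = np.array([1.0 / freq[l] for l in lengths.tolist()])
    w *= lengths.sum() / (w * lengths).sum()
    return w


def loss_weighted_nll(step_nll, lengths) -> Tensor:
    """Weighted mean of per-step NLLs, (B, T) with per-sample lengths.

    Steps at t >= length are excluded; weights are inverse length-class
    frequencies (see :func:`length_weights`).
    """
    nll = _as_t(step_nll)
    lengths = np.asarray(lengths, dtype=int)
    B, T = nll.shape
    if lengths.shape != (B,):
        raise ValueError("lengths must be (batch,)")
    valid = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
    w = length_weights(lengths)[:, None] * valid
    return (nll * Tensor(w)).sum() / float(valid.sum())


# ----------------------------------------------------------------- train loops
def _split(n: int, test_fraction: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n))) if test_fraction > 0 else 0
    return idx[n_test:], idx[:n_test]


def _static_batch_loss(model, inputs, targets):
    """Forward + loss for one minibatch of a static (Markovian) system."""
    res = model.forward(inputs)
    if model.cfg.stochastic:
        idx = list(model.cfg.target_var_indices)
        tgt = (targets - model.norm.mean[idx]) / model.norm.std[idx]
        return loss_nll_gaussian(res.mu, res.var, tgt), res
    return loss_bce_logits(res.logits, targets[..., None]), res


def train(model, dataset, cfg: TrainConfig,
          epoch_callback=None) -> TrainingLog:
    """Fit `model` on `dataset`; returns the per-epoch training log.

    Dispatches on the dataset type (grid transitions, one-step flock
    transitions, or observation/target windows).  `epoch_callback(epoch,
    model, log_entry)` runs after every epoch, e.g. to record attention
    statistics.
    """
    cfg.validate()
    rng = rng_from(cfg.seed, "train")
    if isinstance(dataset, (CADataset, VicsekDataset)):
        inputs, targets = dataset.inputs, (
            dataset.labels if isinstance(dataset, CADataset) else dataset.targets
        )
    elif isinstance(dataset, AOUPDataset):
        inputs, targets = dataset.inputs, dataset.targets
    else:
        raise TypeError(f"unsupported dataset type {type(dataset).__name__}")

    model.set_normalization(Normalization.fit(inputs))
    train_idx, test_idx = _split(len(dataset), cfg.test_fraction, rng)
    opt = Adam(model.parameters(), lr=cfg.lr)
    sched = ReduceLROnPlateau(opt, factor=cfg.decay_factor,
                              patience=cfg.plateau_patience,
                              threshold=cfg.plateau_threshold)
    log = TrainingLog()

    def batch_loss(bidx, sample_rng=None):
        if isinstance(dataset, AOUPDataset):
            return _window_loss(model, dataset, bidx, cfg, sample_rng)
        return _static_batch_loss(model, inputs[bidx], targets[bidx])[0]

    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        total, count = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            bidx = order[start:start + cfg.batch_size]
            model.zero_grad()
            loss = batch_loss(bidx, rng)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} (lr={opt.lr:.2e})"
                )
            loss.backward()
            opt.step()
            total += float(loss.data) * len(bidx)
            count += len(bidx)
        train_loss = total / max(count, 1)
        if len(test_idx):
            test_loss = float(
                batch_loss(test_idx[:cfg.max_eval_samples], rng).data)
        else:
            test_loss = train_loss
        decayed = sched.step(test_loss)
        entry = dict(epoch=epoch, lr=opt.lr, train_loss=train_loss,
                     test_loss=test_loss, lr_decayed=decayed)
        log.append(**entry)
        if epoch_callback is not None:
            epoch_callback(epoch, model, entry)
    return log


def _window_loss(model, dataset: AOUPDataset, bidx, cfg: TrainConfig,
                 rng: np.random.Generator) -> Tensor:
    """Multi-step NLL over the target window with sampled feedback.

    For the AOUP setting the predicted variables are the full state, so a
    reparameterized sample (mu + sqrt(var) * eps, in normalized units) is
    fed back directly as the next input and gradients flow through the
    whole chain.  With `teacher_forcing` the ground-truth state is fed
    back instead.
    """
    obs = dataset.inputs[bidx]
    tgt = dataset.targets[bidx]
    globals_ = dataset.R[bidx, None] if model.cfg.n_globals else None
    B, T_pred = tgt.shape[0], tgt.shape[1]
    res = model.forward_window(obs, globals_)
    h, c = res._hidden
    idx = list(model.cfg.target_var_indices)
    losses = []
    for t in range(T_pred):
        tgt_n = (tgt[:, t][..., idx] - model.norm.mean[idx]) / model.norm.std[idx]
        losses.append(loss_nll_gaussian(res.mu, res.var, tgt_n))
        if t == T_pred - 1:
            break
        if cfg.teacher_forcing:
            x_next = Tensor(model.normalize(tgt[:, t]))
        else:
            eps = rng.normal(size=res.mu.shape)
            x_next = res.mu + ad.sqrt(res.var) * Tensor(eps)
        h, c = model.encode_step(x_next, h, c)
        res = model.predict(h, globals_)
    total = losses[0]
    for l in losses[1:]:
        total = total + l
    return total / float(len(losses))


# --------------------------------------------------------------------- rollout
def rollout(model: RecurrentAgentNet, observed: np.ndarray, n_steps: int,
            seed: int = 0, globals_=None, sample_mode: str = "sample"):
    """Iteratively sample future states from a recurrent model.

    observed: (T_obs, n, d) or (B, T_obs, n, d) raw-unit window.
    Returns (samples, attention_history): samples (B, n_steps, n, d) in raw
    units and one (B, n, n-1, Q) attention tensor per predicted step.
    """
    rng = rng_from(seed, "rollout")
    observed = np.asarray(observed, dtype=float)
    squeeze = observed.ndim == 3
    if squeeze:
        observed = observed[None]
    if sorted(model.cfg.target_var_indices) != list(range(model.cfg.input_dims)):
        raise ValueError("rollout requires the model to predict the full state")
    samples, attn = [], []
    res = model.forward_window(observed, globals_)
    h, c = res._hidden
    for _ in range(int(n_steps)):
        attn.append(res.attention())
        if sample_mode == "mean":
            step = res.mean()
        elif sample_mode == "sample":
            step = res.sample(rng)
        else:
            raise ValueError("sample_mode must be 'sample' or 'mean'")
        samples.append(step)
        h, c = model.encode_step(Tensor(model.normalize(step)), h, c)
        res = model.predict(h, globals_)
    n = observed.shape[2]
    out = (np.stack(samples, axis=1) if samples
           else np.empty((observed.shape[0], 0, n, observed.shape[3])))
    if squeeze:
        out = out[0]
    return out, attn


# ------------------------------------------------------------------ evaluation
def ca_accuracy(model: AgentNet, dataset: CADataset,
                batch_size: int = 32) -> float:
    """Per-cell binary accuracy at threshold 0.5 on held-out grids."""
    correct, total = 0, 0
    for start in range(0, len(dataset), batch_size):
        sl = slice(start, start + batch_size)
        prob = model.forward(dataset.inputs[sl]).prob()[..., 0]
        pred = (prob > 0.5).astype(float)
        correct += (pred == dataset.labels[sl]).sum()
        total += pred.size
    return correct / total


def vicsek_test_nll(model: AgentNet, dataset: VicsekDataset) -> float:
    loss, _ = _static_batch_loss(model, dataset.inputs, dataset.targets)
    return float(loss.data)
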