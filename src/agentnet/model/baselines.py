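"""Baseline predictors sharing AgentNet's I/O contract.

* MLPBaseline / LSTMBaseline — no attention core at all: each agent's
  prediction depends only on its own (encoded) state, with a widened
  decoder [2 x value, 256, 256, out] to compensate for the missing
  module (the context half of the decoder input is zero).
* GATBaseline — a single inner-product attention value per ordered pair
  (128-dimensional key/query projections, softmax-normalized over
  neighbors), shared by all output variables.
* GAT3Baseline — the 3-head variant; head contexts are concatenated and
  mixed back to the value width before decoding.
"""

from __future__ import annotations

import numpy as np

from ..nn import autodiff as ad
from ..nn import LSTMCell, Linear, MLP, Module
from ..nn.autodiff import Tensor
from .agentnet import ForwardResult, VAR_FLOOR, _prepare
from .config import ModelConfig, Normalization


class _SelfOnlyHead(Module):
    """Widened per-variable decoders + Gaussian heads, zero context."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dt = cfg.np_dtype
        self.cfg = cfg
        dims = [2 * cfg.att_dims, 256, 256, cfg.decoder_out]
        self.decoders = [MLP(dims, rng, dtype=dt) for _ in range(cfg.n_out_vars)]
        if cfg.stochastic:
            head = [cfg.decoder_out, cfg.head_hidden, 1]
            self.mean_heads = [MLP(head, rng, dtype=dt)
                               for _ in range(cfg.n_out_vars)]
            self.var_heads = [MLP(head, rng, dtype=dt)
                              for _ in range(cfg.n_out_vars)]

    def __call__(self, V: Tensor) -> dict:
        cfg = self.cfg
        zeros = Tensor(np.zeros_like(V.data))
        dec_in = ad.concat([V, zeros], axis=-1)
        outs, mus, vars_ = [], [], []
        for q in range(cfg.n_out_vars):
            d_q = self.decoders[q](dec_in)
            if cfg.stochastic:
                mus.append(self.mean_heads[q](d_q))
                vars_.append(ad.softplus(self.var_heads[q](d_q)) + VAR_FLOOR)
            else:
                outs.append(d_q)
        if cfg.stochastic:
            return {"mu": ad.concat(mus, -1), "var": ad.concat(vars_, -1)}
        return {"logits": ad.concat(outs, -1)}


class MLPBaseline(Module):
    """Feedforward predictor that ignores every other agent."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.norm = Normalization.identity(cfg.input_dims)
        self.encoder = MLP([cfg.input_dims, cfg.encoder_hidden,
                            3 * cfg.att_dims], rng, dtype=cfg.np_dtype)
        self.head = _SelfOnlyHead(cfg, rng)

    def set_normalization(self, norm):
        self.norm = norm

    def forward(self, states, globals_=None, presence=None) -> ForwardResult:
        states, squeeze = _prepare(states, self.cfg)
        Xn = self.norm.apply(states).astype(self.cfg.np_dtype)
        enc = self.encoder(Tensor(Xn))
        V = enc[..., 2 * self.cfg.att_dims:]
        out = self.head(V)
        return ForwardResult(config=self.cfg, norm=self.norm, alpha=[],
                             squeeze=squeeze, **out)

    __call__ = forward


class LSTMBaseline(Module):
    """Recurrent predictor without attention (agents stay independent)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        cfg.validate()
        rng = np.random.default_rng(seed)
        dt = cfg.np_dtype
        self.cfg = cfg
        self.norm = Normalization.identity(cfg.input_dims)
        self.pre = Linear(cfg.input_dims, cfg.encoder_hidden, rng, dtype=dt)
        self.lstm = LSTMCell(cfg.encoder_hidden, cfg.lstm_hidden, rng, dtype=dt)
        self.proj = Linear(cfg.lstm_hidden, 3 * cfg.att_dims, rng, dtype=dt)
        H = cfg.lstm_hidden
        self.init_h = MLP([cfg.input_dims, H, H], rng, dtype=dt)
        self.init_c = MLP([cfg.input_dims, H, H], rng, dtype=dt)
        self.head = _SelfOnlyHead(cfg, rng)

    def set_normalization(self, norm):
        self.norm = norm

    def forward_window(self, states, globals_=None) -> ForwardResult:
        states = np.asarray(states, dtype=float)
        squeeze = states.ndim == 3
        if squeeze:
            states = states[None]
        Xn = self.norm.apply(states).astype(self.cfg.np_dtype)
        h = self.init_h(Tensor(Xn[:, 0]))
        c = self.init_c(Tensor(Xn[:, 0]))
        for t in range(states.shape[1]):
            h, c = self.lstm(ad.mish(self.pre(Tensor(Xn[:, t]))), h, c)
        V = self.proj(h)[..., 2 * self.cfg.att_dims:]
        out = self.head(V)
        result = ForwardResult(config=self.cfg, norm=self.norm, alpha=[],
                               squeeze=squeeze, **out)
        result._hidden = (h, c)
        return result

    __call__ = forward_window


def _softmax_offdiag(scores: Tensor, n: int) -> Tensor:
    """Softmax over sources j != i (diagonal excluded), batched (B, n, n)."""
    shift = scores - np.max(scores.data, axis=-1, keepdims=True)
    e = ad.exp(shift)
    mask = Tensor(np.broadcast_to(1.0 - np.eye(n, dtype=scores.dtype),
                                  scores.shape))
    e = e * mask
    return e / (e.sum(axis=-1, keepdims=True) + 1e-12)


class GATBaseline(Module):
    """Single inner-product attention per pair, shared across variables."""

    n_heads = 1

    def __init__(self, cfg: ModelConfig, seed: int = 0, proj_dim: int = 128):
        cfg.validate()
        rng = np.random.default_rng(seed)
        dt = cfg.np_dtype
        self.cfg = cfg
        self.proj_dim = proj_dim
        self.norm = Normalization.identity(cfg.input_dims)
        self.encoder = MLP([cfg.input_dims, cfg.encoder_hidden,
                            3 * cfg.att_dims], rng, dtype=dt)
        self.key_proj = Linear(cfg.att_dims, proj_dim, rng, dtype=dt)
        self.query_proj = Linear(cfg.att_dims, proj_dim, rng, dtype=dt)
        from .agentnet import VariableWiseAttentionCore

        self.core = VariableWiseAttentionCore(cfg, rng)

    def set_normalization(self, norm):
        self.norm = norm

    def attention_weights(self, K: Tensor, Qr: Tensor) -> Tensor:
        k = self.key_proj(K)
        q = self.query_proj(Qr)
        scores = ad.matmul(k, q.swapaxes(-1, -2)) / np.sqrt(self.proj_dim)
        return _softmax_offdiag(scores, K.shape[1])

    def forward(self, states, globals_=None, presence=None) -> ForwardResult:
        cfg = self.cfg
        states, squeeze = _prepare(states, cfg)
        Xn = self.norm.apply(states).astype(cfg.np_dtype)
        A = cfg.att_dims
        enc = self.encoder(Tensor(Xn))
        K, Qr, V = enc[..., :A], enc[..., A:2 * A], enc[..., 2 * A:]
        w = self.attention_weights(K, Qr)
        # softmax weights are already normalized: plain weighted sum
        context = ad.matmul(w, V)
        dec_in = ad.concat([V, context], axis=-1)
        outs, mus, vars_ = [], [], []
        for q in range(cfg.n_out_vars):
            d_q = self.core.decoders[q](dec_in)
            if cfg.stochastic:
                mus.append(self.core.mean_heads[q](d_q))
                vars_.append(ad.softplus(self.core.var_heads[q](d_q)) + VAR_FLOOR)
            else:
                outs.append(d_q)
        out = ({"mu": ad.concat(mus, -1), "var": ad.concat(vars_, -1)}
               if cfg.stochastic else {"logits": ad.concat(outs, -1)})
        return ForwardResult(config=cfg, norm=self.norm, alpha=[w],
                             squeeze=squeeze, **out)

    __call__ = forward


class GAT3Baseline(Module):
    """Three-head inner-product attention; heads mixed before decoding."""

    n_heads = 3

    def __init__(self, cfg: ModelConfig, seed: int = 0, head_dim: int = 12):
        cfg.validate()
        rng = np.random.default_rng(seed)
        dt = cfg.np_dtype
        self.cfg = cfg
        self.head_dim = head_dim
        self.norm = Normalization.identity(cfg.input_dims)
        self.encoder = MLP([cfg.input_dims, cfg.encoder_hidden,
                            3 * cfg.att_dims], rng, dtype=dt)
        self.key_proj = Linear(cfg.att_dims, self.n_heads * head_dim, rng, dtype=dt)
        self.query_proj = Linear(cfg.att_dims, self.n_heads * head_dim, rng,
                                 dtype=dt)
        self.value_proj = Linear(cfg.att_dims, self.n_heads * head_dim, rng,
                                 dtype=dt)
        self.mix = Linear(self.n_heads * head_dim, cfg.att_dims, rng, dtype=dt)
        from .agentnet import VariableWiseAttentionCore

        self.core = VariableWiseAttentionCore(cfg, rng)

    def set_normalization(self, norm):
        self.norm = norm

    def forward(self, states, globals_=None, presence=None) -> ForwardResult:
        cfg = self.cfg
        states, squeeze = _prepare(states, cfg)
        Xn = self.norm.apply(states).astype(cfg.np_dtype)
        A, hd = cfg.att_dims, self.head_dim
        n = states.shape[1]
        enc = self.encoder(Tensor(Xn))
        K, Qr, V = enc[..., :A], enc[..., A:2 * A], enc[..., 2 * A:]
        k = self.key_proj(K)
        q = self.query_proj(Qr)
        v = self.value_proj(V)
        weights, contexts = [], []
        for head in range(self.n_heads):
            sl = slice(head * hd, (head + 1) * hd)
            scores = ad.matmul(k[..., sl], q[..., sl].swapaxes(-1, -2))
            scores = scores / np.sqrt(hd)
            w = _softmax_offdiag(scores, n)
            weights.append(w)
            contexts.append(ad.matmul(w, v[..., sl]))
        mixed = self.mix(ad.concat(contexts, axis=-1))
        dec_in = ad.concat([V, mixed], axis=-1)
        outs, mus, vars_ = [], [], []
        for qv in range(cfg.n_out_vars):
            d_q = self.core.decoders[qv](dec_in)
            if cfg.stochastic:
                mus.append(self.core.mean_heads[qv](d_q))
                vars_.append(ad.softplus(self.core.var_heads[qv](d_q)) + VAR_FLOOR)
            else:
                outs.append(d_q)
        out = ({"mu": ad.concat(mus, -1), "var": ad.concat(vars_, -1)}
               if cfg.stochastic else {"logits": ad.concat(outs, -1)})
        return ForwardResult(config=cfg, norm=self.norm, alpha=weights,
                             squeeze=squeeze, **out)

    __call__ = forward
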