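"""AgentNet: encoder, variable-wise neural attention, separated decoders.

The network predicts each agent's next state from the states of all
agents.  One encoder produces key/query/value vectors per agent; for every
output variable q an independent attention MLP maps (key_i, query_j,
globals) to a coefficient a_ij^q, squashed by a sigmoid into
alpha_ij^q in (0, 1) — deliberately *not* softmax-normalized across
neighbors, so alpha reads as an absolute interaction strength.  Each
variable's context is the mean over j != i of alpha_ij^q * value_j, and a
per-variable decoder sees only its own context, so attention for variable
q provably cannot influence any other variable's prediction.

Stochastic variants end in separate mean/variance heads per variable
(variance made positive by softplus with a small floor); deterministic
variants emit logits.  A recurrent variant runs the encoder through an
LSTM so that hidden variables (e.g. the AOUP propulsion force) can be
inferred from past observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import autodiff as ad
from ..nn import LSTMCell, Linear, MLP, Module
from ..nn.autodiff import Tensor
from .config import ModelConfig, Normalization

VAR_FLOOR = 1e-6


@dataclass
class ForwardResult:
    """Output of one forward pass: predictions plus the attention tensor."""

    config: ModelConfig
    norm: Normalization
    alpha: list          # per output variable: Tensor (B, n, n)
    logits: Tensor | None = None
    mu: Tensor | None = None        # normalized units
    var: Tensor | None = None       # normalized units
    squeeze: bool = False

    @property
    def n_agents(self) -> int:
        a = self.logits if self.logits is not None else self.mu
        return a.shape[1]

    def _maybe_squeeze(self, arr: np.ndarray) -> np.ndarray:
        return arr[0] if self.squeeze else arr

    def alpha_full(self) -> np.ndarray:
        """(B, n, n, Q) attention weights with a zeroed diagonal."""
        if not self.alpha:
            raise ValueError("this model variant computes no attention")
        arrs = [a.data for a in self.alpha]
        out = np.stack(arrs, axis=-1).astype(float).copy()
        idx = np.arange(out.shape[1])
        out[:, idx, idx, :] = 0.0
        return self._maybe_squeeze(out)

    def attention(self) -> np.ndarray:
        """(B, n, n-1, Q): per target i, sources j != i in roster order."""
        if not self.alpha:
            raise ValueError("this model variant computes no attention")
        full = np.stack([a.data for a in self.alpha], axis=-1)
        B, n = full.shape[:2]
        keep = ~np.eye(n, dtype=bool)
        out = full[:, keep, :].reshape(B, n, n - 1, full.shape[-1])
        return self._maybe_squeeze(out)

    def prob(self) -> np.ndarray:
        """Alive probabilities for the deterministic/binary setting."""
        with np.errstate(over="ignore"):
            prob = 1.0 / (1.0 + np.exp(-self.logits.data))
        return self._maybe_squeeze(prob)

    def mean(self) -> np.ndarray:
        """Predicted means in raw state units."""
        idx = self.config.target_var_indices
        return self._maybe_squeeze(self.norm.invert(self.mu.data, idx))

    def variance(self) -> np.ndarray:
        """Predicted variances in raw state units squared."""
        idx = list(self.config.target_var_indices)
        return self._maybe_squeeze(self.var.data * self.norm.std[idx] ** 2)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        mu, var = self.mean(), self.variance()
        return rng.normal(mu, np.sqrt(var))


class VariableWiseAttentionCore(Module):
    """Attention MLPs, per-variable decoders and Gaussian heads."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dt = cfg.np_dtype
        self.cfg = cfg
        Q = cfg.n_out_vars
        self.att_mlps = [MLP(cfg.att_mlp, rng, dtype=dt) for _ in range(Q)]
        if cfg.att_bias_init:
            # start from a weak-coupling prior: alpha near zero at init
            for mlp in self.att_mlps:
                mlp.layers[-1].bias.data[...] = cfg.att_bias_init
        if cfg.per_variable_decoder:
            dec_dims = [2 * cfg.att_dims, cfg.decoder_hidden, cfg.decoder_out]
            self.decoders = [MLP(dec_dims, rng, dtype=dt) for _ in range(Q)]
        else:
            # single decoder over all variable contexts; forfeits the
            # strict variable-separation property
            dec_dims = [(1 + Q) * cfg.att_dims, cfg.decoder_hidden,
                        cfg.decoder_out]
            self.decoders = [MLP(dec_dims, rng, dtype=dt)]
        if cfg.stochastic:
            head = [cfg.decoder_out, cfg.head_hidden, 1]
            self.mean_heads = [MLP(head, rng, dtype=dt) for _ in range(Q)]
            self.var_heads = [MLP(head, rng, dtype=dt) for _ in range(Q)]

    # ------------------------------------------------------------- attention
    def attention_full(self, K: Tensor, Qr: Tensor, globals_t: np.ndarray | None,
                       att_bias=None) -> list[Tensor]:
        B, n, A = K.shape
        Ki = ad.broadcast_to(K.reshape(B, n, 1, A), (B, n, n, A))
        Qj = ad.broadcast_to(Qr.reshape(B, 1, n, A), (B, n, n, A))
        parts = [Ki, Qj]
        if self.cfg.n_globals:
            if globals_t is None:
                raise ValueError("model expects global variables")
            g = np.asarray(globals_t, dtype=K.dtype).reshape(B, 1, 1, -1)
            parts.append(ad.broadcast_to(Tensor(g), (B, n, n, g.shape[-1])))
        att_in = ad.concat(parts, axis=-1)
        alphas = []
        for q, mlp in enumerate(self.att_mlps):
            a = mlp(att_in)
            if att_bias is not None:
                a = a + float(att_bias[q])
            alphas.append(ad.sigmoid(a).reshape(B, n, n))
        return alphas

    def attention_dedup(self, K_u: Tensor, Q_u: Tensor, ki: np.ndarray,
                        qi: np.ndarray, pinv: np.ndarray,
                        shape: tuple, att_bias=None) -> list[Tensor]:
        """Attention over unique (key state, query state) pairs only."""
        B, n = shape
        att_in = ad.concat(
            [ad.gather_rows(K_u, ki), ad.gather_rows(Q_u, qi)], axis=-1
        )
        alphas = []
        for q, mlp in enumerate(self.att_mlps):
            a_u = mlp(att_in)                        # (P, 1)
            if att_bias is not None:
                a_u = a_u + float(att_bias[q])
            a = ad.gather_rows(a_u, pinv).reshape(B, n, n)
            alphas.append(ad.sigmoid(a))
        return alphas

    # ---------------------------------------------------------------- decode
    def decode(self, V: Tensor, alphas: list[Tensor],
               presence: np.ndarray | None) -> dict:
        cfg = self.cfg
        B, n, A = V.shape
        eye = np.eye(n, dtype=V.dtype)
        if presence is None:
            pair_mask = np.broadcast_to(1.0 - eye, (B, n, n))
            denom = np.full((B, 1, 1), max(n - 1, 1), dtype=V.dtype)
        else:
            pm = presence.astype(V.dtype)
            pair_mask = (1.0 - eye) * pm[:, None, :] * pm[:, :, None]
            counts = pm.sum(axis=1)
            denom = np.maximum(counts - 1.0, 1.0)[:, None, None]
        mask_t = Tensor(np.ascontiguousarray(pair_mask))
        contexts = []
        for q in range(cfg.n_out_vars):
            weighted = alphas[q] * mask_t
            contexts.append(ad.matmul(weighted, V) / Tensor(denom))
        if not cfg.per_variable_decoder:
            d = self.decoders[0](ad.concat([V] + contexts, axis=-1))
            if not cfg.stochastic:
                return {"logits": d}
            mus = [h(d) for h in self.mean_heads]
            vars_ = [ad.softplus(h(d)) + VAR_FLOOR for h in self.var_heads]
            return {"mu": ad.concat(mus, axis=-1),
                    "var": ad.concat(vars_, axis=-1)}
        outs = []
        mus, vars_ = [], []
        for q in range(cfg.n_out_vars):
            dec_in = ad.concat([V, contexts[q]], axis=-1)
            d_q = self.decoders[q](dec_in)           # (B, n, D)
            if cfg.stochastic:
                mus.append(self.mean_heads[q](d_q))
                vars_.append(ad.softplus(self.var_heads[q](d_q)) + VAR_FLOOR)
            else:
                outs.append(d_q)
        if cfg.stochastic:
            return {"mu": ad.concat(mus, axis=-1), "var": ad.concat(vars_, axis=-1)}
        return {"logits": ad.concat(outs, axis=-1)}


def _prepare(states: np.ndarray, cfg: ModelConfig) -> tuple[np.ndarray, bool]:
    states = np.asarray(states, dtype=float)
    squeeze = states.ndim == 2
    if squeeze:
        states = states[None]
    if states.ndim != 3 or states.shape[-1] != cfg.input_dims:
        raise ValueError(
            f"states must be (batch, agents, {cfg.input_dims}), got {states.shape}"
        )
    if not np.isfinite(states).all():
        raise ValueError("states contain NaN or infinite values")
    return states, squeeze


class AgentNet(Module):
    """Feedforward AgentNet for Markovian systems (CA, Vicsek)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        cfg.validate()
        rng = np.random.default_rng(seed)
        dt = cfg.np_dtype
        self.cfg = cfg
        self.norm = Normalization.identity(cfg.input_dims)
        self.encoder = MLP(
            [cfg.input_dims, cfg.encoder_hidden, 3 * cfg.att_dims], rng, dtype=dt
        )
        self.core = VariableWiseAttentionCore(cfg, rng)

    def set_normalization(self, norm: Normalization) -> None:
        self.norm = norm

    def forward(self, states: np.ndarray, globals_=None, presence=None,
                att_bias=None) -> ForwardResult:
        cfg = self.cfg
        states, squeeze = _prepare(states, cfg)
        B, n, _ = states.shape
        Xn = self.norm.apply(states).astype(cfg.np_dtype)
        A = cfg.att_dims

        use_dedupe = (
            cfg.dedupe_pairs and presence is None and not cfg.n_globals
        )
        if use_dedupe:
            flat = Xn.reshape(B * n, -1)
            uniq, inv = np.unique(flat, axis=0, return_inverse=True)
            use_dedupe = uniq.shape[0] <= 0.5 * flat.shape[0]
        if use_dedupe:
            enc_u = self.encoder(Tensor(uniq))
            K_u, Q_u, V_u = (
                enc_u[:, :A], enc_u[:, A:2 * A], enc_u[:, 2 * A:]
            )
            U = uniq.shape[0]
            inv2 = inv.reshape(B, n)
            codes = inv2[:, :, None].astype(np.int64) * U + inv2[:, None, :]
            flat_codes = codes.ravel()
            if U * U <= 4 * flat_codes.size:
                # dense code space: flag-array unique beats sorting
                flags = np.zeros(U * U, dtype=bool)
                flags[flat_codes] = True
                up = np.flatnonzero(flags)
                lookup = np.empty(U * U, dtype=np.int64)
                lookup[up] = np.arange(up.size)
                pinv = lookup[flat_codes]
            else:
                up, pinv = np.unique(flat_codes, return_inverse=True)
            alphas = self.core.attention_dedup(
                K_u, Q_u, up // U, up % U, pinv, (B, n), att_bias
            )
            V = ad.gather_rows(V_u, inv).reshape(B, n, A)
        else:
            enc = self.encoder(Tensor(Xn))
            K, Qr, V = (
                enc[..., :A], enc[..., A:2 * A], enc[..., 2 * A:]
            )
            alphas = self.core.attention_full(K, Qr, globals_, att_bias)
        out = self.core.decode(V, alphas, presence)
        return ForwardResult(config=cfg, norm=self.norm, alpha=alphas,
                             squeeze=squeeze, **out)

    __call__ = forward


class RecurrentAgentNet(Module):
    """AgentNet with an LSTM encoder for systems with memory (AOUP, birds).

    Hidden and cell states (width `lstm_hidden`) are initialized from an
    agent's first observed state by two dedicated MLPs trained jointly
    with the rest of the network.
    """

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
        self.core = VariableWiseAttentionCore(cfg, rng)

    def set_normalization(self, norm: Normalization) -> None:
        self.norm = norm

    # ----------------------------------------------------------- primitives
    def normalize(self, states: np.ndarray) -> np.ndarray:
        return self.norm.apply(states).astype(self.cfg.np_dtype)

    def init_hidden(self, first_states_norm: Tensor) -> tuple[Tensor, Tensor]:
        return self.init_h(first_states_norm), self.init_c(first_states_norm)

    def encode_step(self, x_norm: Tensor, h: Tensor, c: Tensor):
        return self.lstm(ad.mish(self.pre(x_norm)), h, c)

    def predict(self, h: Tensor, globals_=None, presence=None,
                att_bias=None, squeeze=False) -> ForwardResult:
        A = self.cfg.att_dims
        enc = self.proj(h)
        K, Qr, V = enc[..., :A], enc[..., A:2 * A], enc[..., 2 * A:]
        alphas = self.core.attention_full(K, Qr, globals_, att_bias)
        out = self.core.decode(V, alphas, presence)
        return ForwardResult(config=self.cfg, norm=self.norm, alpha=alphas,
                             squeeze=squeeze, **out)

    # ------------------------------------------------------------- windowed
    def forward_window(self, states: np.ndarray, globals_=None,
                       att_bias=None) -> ForwardResult:
        """Encode an observation window (B, T, n, d); predict the state
        following the last observed step."""
        cfg = self.cfg
        states = np.asarray(states, dtype=float)
        squeeze = states.ndim == 3
        if squeeze:
            states = states[None]
        if states.ndim != 4 or states.shape[-1] != cfg.input_dims:
            raise ValueError("window must be (batch, steps, agents, input_dims)")
        if not np.isfinite(states).all():
            raise ValueError("states contain NaN or infinite values")
        Xn = self.normalize(states)
        h, c = self.init_hidden(Tensor(Xn[:, 0]))
        for t in range(states.shape[1]):
            h, c = self.encode_step(Tensor(Xn[:, t]), h, c)
        result = self.predict(h, globals_, att_bias=att_bias, squeeze=squeeze)
        result._hidden = (h, c)  # kept for continued rollout
        return result

    __call__ = forward_window
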