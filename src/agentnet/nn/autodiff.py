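"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The network components in this package (MLP encoders/decoders, the neural
attention core, LSTM cells) only need a small set of differentiable
primitives, so we keep a single-file tape-based engine: every op builds a
:class:`Tensor` holding the forward value, its parents and a closure that
accumulates gradients into the parents.  Broadcasting follows NumPy rules;
gradients of broadcast operands are reduced back to the operand shape.

Dtypes are propagated from the inputs (float32 training, float64 for
finite-difference checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "sigmoid",
    "tanh",
    "softplus",
    "mish",
    "exp",
    "log",
    "sqrt",
    "square",
    "matmul",
    "broadcast_to",
    "gather_rows",
    "clip",
    "stack_last",
]


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x), requires_grad=False)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were introduced/stretched by broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray, fresh: bool = False) -> None:
        """Add `grad` into this tensor's gradient buffer.

        `fresh=True` promises the caller hands over a newly allocated
        array that nothing else aliases, letting us adopt it without a
        defensive copy.
        """
        if self.grad is None:
            if fresh and grad.dtype == self.data.dtype:
                self.grad = grad
            else:
                self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order over the subgraph that requires grad
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad

        def bw(g):
            if self.requires_grad:
                ga = _unbroadcast(g, self.data.shape)
                self._accumulate(ga, fresh=ga is not g)
            if other.requires_grad:
                gb = _unbroadcast(g, other.data.shape)
                other._accumulate(gb, fresh=gb is not g)

        return Tensor(out_data, req, (self, other), bw if req else None)

    __radd__ = __add__

    def __neg__(self):
        req = self.requires_grad

        def bw(g):
            self._accumulate(-g, fresh=True)

        return Tensor(-self.data, req, (self,), bw if req else None)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape),
                                 fresh=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape),
                                  fresh=True)

        return Tensor(out_data, req, (self, other), bw if req else None)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data
        req = self.requires_grad or other.requires_grad

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape),
                                 fresh=True)
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2,
                                 other.data.shape), fresh=True
                )

        return Tensor(out_data, req, (self, other), bw if req else None)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out_data = self.data**p
        req = self.requires_grad

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1), fresh=True)

        return Tensor(out_data, req, (self,), bw if req else None)

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        req = self.requires_grad
        orig = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(orig))

        return Tensor(out_data, req, (self,), bw if req else None)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)
        req = self.requires_grad

        def bw(g):
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor(out_data, req, (self,), bw if req else None)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        req = self.requires_grad
        shape = self.data.shape
        parts = idx if isinstance(idx, tuple) else (idx,)
        fancy = any(isinstance(p, (np.ndarray, list)) for p in parts)

        def bw(g):
            full = np.zeros(shape, dtype=g.dtype)
            if fancy:
                np.add.at(full, idx, g)
            else:
                full[idx] += g
            self._accumulate(full, fresh=True)

        return Tensor(out_data, req, (self,), bw if req else None)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        req = self.requires_grad
        shape = self.data.shape

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).copy(), fresh=True)
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, shape).copy(), fresh=True)

        return Tensor(out_data, req, (self,), bw if req else None)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)


# ------------------------------------------------------------------ functions
def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data
    req = a.requires_grad or b.requires_grad

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape), fresh=True)
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape), fresh=True)

    return Tensor(out_data, req, (a, b), bw if req else None)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        splits = np.cumsum(sizes)[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor(out_data, req, tuple(tensors), bw if req else None)


def stack_last(tensors) -> Tensor:
    """Stack scalars-per-row tensors along a new final axis."""
    expanded = [t.reshape(t.shape + (1,)) for t in tensors]
    return concat(expanded, axis=-1)


def broadcast_to(t: Tensor, shape) -> Tensor:
    t = _as_tensor(t)
    out_data = np.broadcast_to(t.data, shape)
    req = t.requires_grad

    def bw(g):
        gt = _unbroadcast(g, t.data.shape)
        t._accumulate(gt, fresh=gt is not g)

    return Tensor(out_data, req, (t,), bw if req else None)


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows along axis 0; backward scatter-adds into the source.

    Fast path for 1- and 2-D sources via bincount.
    """
    idx = np.asarray(idx)
    out_data = t.data[idx]
    req = t.requires_grad
    n = t.data.shape[0]

    def bw(g):
        if t.data.ndim == 2:
            flat_idx = idx.reshape(-1)
            gf = g.reshape(-1, t.data.shape[1])
            acc = np.empty_like(t.data)
            for c in range(t.data.shape[1]):
                acc[:, c] = np.bincount(flat_idx, weights=gf[:, c], minlength=n)
            t._accumulate(acc, fresh=True)
        else:
            acc = np.zeros_like(t.data)
            np.add.at(acc, idx, g)
            t._accumulate(acc, fresh=True)

    return Tensor(out_data, req, (t,), bw if req else None)


def _unary(t: Tensor, out_data: np.ndarray, dlocal: np.ndarray) -> Tensor:
    req = t.requires_grad

    def bw(g):
        t._accumulate(g * dlocal, fresh=True)

    return Tensor(out_data, req, (t,), bw if req else None)


def exp(t: Tensor) -> Tensor:
    t = _as_tensor(t)
    out = np.exp(t.data)
    _flush_tiny(out)
    return _unary(t, out, out)


def log(t: Tensor) -> Tensor:
    t = _as_tensor(t)
    return _unary(t, np.log(t.data), 1.0 / t.data)


def sqrt(t: Tensor) -> Tensor:
    t = _as_tensor(t)
    out = np.sqrt(t.data)
    return _unary(t, out, 0.5 / out)


def square(t: Tensor) -> Tensor:
    t = _as_tensor(t)
    return _unary(t, t.data**2, 2.0 * t.data)


def _flush_tiny(arr: np.ndarray, tol: float = 1e-30) -> np.ndarray:
    """Zero magnitudes below `tol` in place.

    Deeply saturated activations otherwise fill gradient arrays with
    float32 subnormals, which many CPUs process an order of magnitude
    more slowly; the flushed values are far below the resolution of any
    downstream float32 sum.
    """
    if arr.ndim:
        np.copyto(arr, 0.0, where=np.abs(arr) < tol)
    return arr


def sigmoid(t: Tensor) -> Tensor:
    t = _as_tensor(t)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-t.data))
    _flush_tiny(out)
    return _unary(t, out, out * (1.0 - out))


def tanh(t: Tensor) -> Tensor:
    t = _as_tensor(t)
    out = np.tanh(t.data)
    return _unary(t, out, 1.0 - out**2)


def _softplus_np(x: np.ndarray) -> np.ndarray:
    # max(x, 0) + log1p(exp(-|x|)): stable and faster than np.logaddexp
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def softplus(t: Tensor) -> Tensor:
    t = _as_tensor(t)
    out = _softplus_np(t.data)
    _flush_tiny(out)
    with np.errstate(over="ignore"):
        grad = 1.0 / (1.0 + np.exp(-t.data))
    _flush_tiny(grad)
    return _unary(t, out, grad)


try:  # fused elementwise kernel; plain NumPy otherwise
    import numba as _nb

    @_nb.njit(fastmath=True, cache=False, error_model="numpy")
    def _mish_flat(xr, yr, dyr):
        # one exp per element: with t = exp(-|x|), both sigmoid(x) and
        # exp(-softplus(x)) are rational in t, hence so is tanh(softplus(x))
        for i in range(xr.shape[0]):
            xi = xr[i]
            if xi < -60.0:
                # tail flush: mish(x) ~ x*exp(x) is below 1e-24 here and
                # would otherwise seed slow float32 subnormals downstream
                yr[i] = 0.0
                dyr[i] = 0.0
                continue
            t = np.exp(-abs(xi))
            inv = 1.0 / (1.0 + t)
            if xi > 0.0:
                u = t * inv       # exp(-softplus(x))
                sg = inv          # sigmoid(x)
            else:
                u = inv
                sg = t * inv
            u2 = u * u
            th = (1.0 - u2) / (1.0 + u2)
            yr[i] = xi * th
            dyr[i] = th + xi * (1.0 - th * th) * sg

    def _mish_kernel(x):
        y = np.empty_like(x)
        dy = np.empty_like(x)
        _mish_flat(x.reshape(-1), y.reshape(-1), dy.reshape(-1))
        return y, dy

    # warm both float dtypes so compilation happens at import, not mid-run
    _mish_kernel(np.zeros(1, dtype=np.float64))
    _mish_kernel(np.zeros(1, dtype=np.float32))
except Exception:  # pragma: no cover - numba is optional
    _mish_kernel = None


def mish(t: Tensor) -> Tensor:
    """Mish activation x * tanh(softplus(x)), fused forward/derivative."""
    t = _as_tensor(t)
    x = np.ascontiguousarray(t.data)
    if _mish_kernel is not None and x.dtype in (np.float32, np.float64):
        y, dy = _mish_kernel(x)
    else:
        sp = _softplus_np(x)
        th = np.tanh(sp)
        with np.errstate(over="ignore"):
            sg = 1.0 / (1.0 + np.exp(-x))
        y = x * th
        dy = th + x * (1.0 - th * th) * sg
        _flush_tiny(y)
        _flush_tiny(dy)
    return _unary(t, y, dy)


def clip(t: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside the interval."""
    t = _as_tensor(t)
    out = np.clip(t.data, lo, hi)
    mask = ((t.data > lo) & (t.data < hi)).astype(t.data.dtype)
    return _unary(t, out, mask)
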