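"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to train a small transformer encoder on CPU: broadcast
aware elementwise ops, (batched) matmul, softmax, layer norm, embedding
lookup, a gather along the last axis (used for relative-position attention
terms), and fused classification losses.  Gradients accumulate into
``Tensor.grad``; ``backward`` runs a topological sweep.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    def backward(self) -> None:
        topo, seen = [], set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    @property
    def shape(self):
        return self.data.shape

    # -- elementwise -------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar: weak promotion keeps dtype
            def backward_s(g):
                self._accum(g)

            return Tensor._make(self.data + other, (self,), backward_s)
        other = self._coerce(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def backward_s(g):
                self._accum(g * other)

            return Tensor._make(self.data * other, (self,), backward_s)
        other = self._coerce(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def tanh(self):
        y = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - y * y))

        return Tensor._make(y, (self,), backward)

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            self._accum(g.swapaxes(a, b))

        return Tensor._make(self.data.swapaxes(a, b), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor._make(self.data[key], (self,), backward)

    def amax(self, axis: int):
        """Maximum over one axis; gradient flows to the (first) argmax."""
        idx = np.expand_dims(self.data.argmax(axis=axis), axis)
        out = np.take_along_axis(self.data, idx, axis=axis).squeeze(axis)

        def backward(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, idx, np.expand_dims(g, axis), axis=axis)
            self._accum(full)

        return Tensor._make(out, (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1):
        data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

        return Tensor._make(data, tuple(tensors), backward)

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = self._coerce(other)

        def backward(g):
            self._accum(_unbroadcast(np.matmul(g, other.data.swapaxes(-1, -2)),
                                     self.data.shape))
            other._accum(_unbroadcast(np.matmul(self.data.swapaxes(-1, -2), g),
                                      other.data.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), backward)

    def __matmul__(self, other):
        return self.matmul(other)

    # -- neural-net primitives ---------------------------------------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            self._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

        return Tensor._make(y, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then scale and shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv

        def backward(g):
            dxhat = g * gamma.data
            dx = inv * (dxhat
                        - dxhat.mean(axis=-1, keepdims=True)
                        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
            self._accum(dx)
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
            beta._accum(_unbroadcast(g, beta.data.shape))

        return Tensor._make(gamma.data * xhat + beta.data,
                            (self, gamma, beta), backward)

    def embedding(self, idx: np.ndarray):
        """Row lookup: self is the (vocab, dim) table, idx an integer array."""
        idx = np.asarray(idx)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx.ravel(), g.reshape(-1, self.data.shape[-1]))
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    def gather_last(self, idx2d: np.ndarray):
        """out[..., i, j] = self[..., i, idx2d[i, j]] — relative-position
        score lookup.  ``self`` has shape (..., L, R); ``idx2d`` is (L, L')."""
        x = self.data
        L, Lp = idx2d.shape
        lead = x.shape[:-2]
        idx_b = np.broadcast_to(idx2d, lead + (L, Lp))
        out = np.take_along_axis(x, idx_b, axis=-1)
        r = x.shape[-1]

        def backward(g):
            # scatter-add expressed as a per-row matmul against a one-hot
            # (Lp, R) selector — far cheaper than np.add.at on large L
            n = int(np.prod(lead)) if lead else 1
            onehot = np.zeros((L, Lp, r), dtype=x.dtype)
            onehot[np.arange(L)[:, None], np.arange(Lp)[None, :], idx2d] = 1.0
            g3 = np.ascontiguousarray(g.reshape(n, L, Lp).transpose(1, 0, 2))
            gx = np.matmul(g3, onehot).transpose(1, 0, 2)  # (n, L, R)
            self._accum(gx.reshape(x.shape))

        return Tensor._make(out, (self,), backward)


# -- fused losses ----------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, targets: np.ndarray,
                          ignore_index: int = -1) -> Tensor:
    """Mean cross-entropy over positions whose target != ignore_index.

    ``logits``: (N, C); ``targets``: (N,) integer class ids.
    """
    targets = np.asarray(targets)
    valid = targets != ignore_index
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid targets for cross-entropy")
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    tgt = np.where(valid, targets, 0)
    picked = logp[np.arange(len(targets)), tgt]
    loss_val = -(picked * valid).sum() / n_valid

    def backward(g):
        p = np.exp(logp)
        p[np.arange(len(targets)), tgt] -= 1.0
        p *= (valid / n_valid)[:, None]
        logits._accum(g * p)

    return Tensor._make(np.asarray(loss_val, dtype=logits.data.dtype),
                        (logits,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable form)."""
    t = np.asarray(targets, dtype=logits.data.dtype)
    x = logits.data
    loss_val = np.mean(np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x))))

    def backward(g):
        sig = 1.0 / (1.0 + np.exp(-x))
        logits._accum(g * (sig - t) / x.size)

    return Tensor._make(np.asarray(loss_val, dtype=logits.data.dtype),
                        (logits,), backward)


# -- optimiser -------------------------------------------------------------

class Adam:
    """Adam with bias correction over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
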