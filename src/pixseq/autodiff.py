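"""Minimal reverse-mode automatic differentiation on numpy arrays.

The recurrent tagger in :mod:`pixseq.model` needs gradients of a masked
log-likelihood through stacked LSTM / IndRNN cells.  This module provides a
small define-by-run tape: :class:`Tensor` wraps an ``ndarray``, records the
operations applied to it, and :meth:`Tensor.backward` accumulates gradients
by reverse topological traversal.  Broadcasting follows numpy semantics; the
backward pass sums gradients over broadcast axes.

Every operation used by the model is gradient-checked against central finite
differences in the test suite, so the training loop is trustworthy by
construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "parameter",
    "concat",
    "stack",
    "embedding_lookup",
    "softmax",
    "softmax_cross_entropy",
    "dropout_mask",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables tape recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the recorded tape
        order, seen = [], set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            ready = all(id(p) in seen or not p.requires_grad for p in node._parents)
            if unvisited and not ready:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                order.append(node)
                stack.pop()
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        grad = np.asarray(grad, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def _binary(self, other, fwd, bwd_self, bwd_other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out_data = fwd(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        out = Tensor(out_data, requires_grad=req, parents=(self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))
            out._backward = backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor(np.asarray(other)).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __truediv__(self, other):
        return self._binary(
            other,
            lambda a, b: a / b,
            lambda g, a, b: g / b,
            lambda g, a, b: -g * a / (b * b),
        )

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out = Tensor(self.data @ other.data, requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accum(g @ other.data.T)
                if other.requires_grad:
                    other._accum(self.data.T @ g)
            out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            def backward(g):
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)
            out._backward = backward
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            def backward(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape))
                else:
                    if not keepdims:
                        g = np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out


def parameter(data, dtype=np.float64) -> Tensor:
    """A trainable leaf tensor."""
    return Tensor(np.asarray(data, dtype=dtype), requires_grad=True)


def concat(tensors, axis=-1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, parents=tuple(tensors))
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]
        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = backward
    return out


def stack(tensors, axis=0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, parents=tuple(tensors))
    if out.requires_grad:
        def backward(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis))
        out._backward = backward
    return out


def embedding_lookup(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather with scatter-add backward (embedding layer)."""
    idx = np.asarray(idx)
    out = Tensor(table.data[idx], requires_grad=table.requires_grad, parents=(table,))
    if out.requires_grad:
        def backward(g):
            full = np.zeros_like(table.data)
            np.add.at(full, idx, g)
            table._accum(full)
        out._backward = backward
    return out


def softmax(logits: np.ndarray, axis=-1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Masked mean negative log-likelihood.

    ``logits``: (..., K); ``targets``: integer array matching the leading
    shape; ``mask``: float/bool array, positions with 0 contribute nothing.
    Fused forward/backward for stability (log-sum-exp trick).
    """
    mask = np.asarray(mask, dtype=logits.data.dtype)
    denom = mask.sum()
    if denom <= 0:
        raise ValueError("softmax_cross_entropy: mask selects no positions")
    p = softmax(logits.data)
    tgt = np.asarray(targets)
    idx = tuple(np.indices(tgt.shape)) + (tgt,)
    # clip for the degenerate all-zero-logit row only; p>0 always here
    nll = -np.log(np.maximum(p[idx], 1e-300))
    loss = (nll * mask).sum() / denom
    out = Tensor(np.asarray(loss), requires_grad=logits.requires_grad, parents=(logits,))
    if out.requires_grad:
        def backward(g):
            grad = p.copy()
            grad[idx] -= 1.0
            grad *= (mask / denom)[..., None]
            logits._accum(g * grad)
        out._backward = backward
    return out


def dropout_mask(shape, rate: float, rng: np.random.Generator, dtype=np.float64) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with probability ``rate``, else 1/(1-rate)."""
    if rate <= 0:
        return np.ones(shape, dtype=dtype)
    keep = (rng.random(shape) >= rate).astype(dtype)
    return keep / (1.0 - rate)
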