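"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The tagging network (BiLSTM, Transformer layer, CRF) is built from the
tensor operations defined here.  The engine is deliberately small: dense
arrays only, tape-based backward pass over a topologically sorted graph,
broadcasting handled by summing gradients back to the parent shape.
Every op used by the network is covered by a numerical gradient check in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack", "Adam", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference paths)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED[-1]
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None
        self.name = name

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=parents, backward=backward)

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data
        need_a, need_b = self.requires_grad, other.requires_grad

        def backward(g):
            a, b = self.data, other.data
            ga = gb = None
            if a.ndim == 1 and b.ndim == 2:
                ga = g @ b.T if need_a else None
                gb = np.outer(a, g) if need_b else None
            elif a.ndim == 2 and b.ndim == 1:
                ga = np.outer(g, b) if need_a else None
                gb = a.T @ g if need_b else None
            elif a.ndim == 1 and b.ndim == 1:
                ga = g * b if need_a else None
                gb = g * a if need_b else None
            else:
                if need_a:
                    ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
                if need_b:
                    gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return (ga, gb)

        return self._make(out_data, (self, other), backward)

    # ---- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        from scipy.special import expit  # overflow-safe logistic

        out_data = expit(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sqrt(self):
        return self**0.5

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def logsumexp(self, axis=-1, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)
        s = np.exp(self.data - m).sum(axis=axis, keepdims=True)
        out_data = (m + np.log(s))
        softmax = np.exp(self.data - out_data)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (g * softmax,)

        return self._make(out_data, (self,), backward)

    def softmax(self, axis=-1):
        return (self - self.logsumexp(axis=axis, keepdims=True)).exp()

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape
        return self._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old_shape),)
        )

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return self._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    # ---- backward pass ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, visited = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                cur, processed = stack.pop()
                if processed:
                    topo.append(cur)
                    continue
                if id(cur) in visited or not cur.requires_grad:
                    continue
                visited.add(id(cur))
                stack.append((cur, True))
                for p in cur._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or pgrad is None:
                    continue
                # fresh arrays come out of every backward closure, so direct
                # assignment (no copy) is safe; accumulation allocates anew
                parent.grad = pgrad if parent.grad is None else parent.grad + pgrad

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor with a freeze flag honoured by optimizers."""

    __slots__ = ("frozen",)

    def __init__(self, data, name="", frozen=False):
        super().__init__(data, requires_grad=True, name=name)
        self.frozen = frozen


def concat(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req, parents=tuple(tensors), backward=backward)


def stack(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req, parents=tuple(tensors), backward=backward)


class Adam:
    """Adam optimizer over a list of Parameters; frozen parameters are skipped.

    Gradients are clipped to a global L2 norm before the update (standard
    practice for recurrent stacks).
    """

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, clip_norm=5.0):
        self.params = [p for p in params if isinstance(p, Parameter)]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self._m = {id(p): np.zeros_like(p.data) for p in self.params}
        self._v = {id(p): np.zeros_like(p.data) for p in self.params}

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        active = [p for p in self.params if not p.frozen and p.grad is not None]
        if self.clip_norm is not None and active:
            total = np.sqrt(sum(float((p.grad**2).sum()) for p in active))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for p in active:
                    p.grad = p.grad * scale
        self.t += 1
        for p in active:
            m = self._m[id(p)] = self.b1 * self._m[id(p)] + (1 - self.b1) * p.grad
            v = self._v[id(p)] = self.b2 * self._v[id(p)] + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
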