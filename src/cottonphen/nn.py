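"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the primitives the segmentation network needs: broadcasted
arithmetic, matmul, reductions, max-pooling (over neighbors and over whole
clouds), row gathering for graph neighborhoods, batch normalization with
running statistics, leaky rectifier, softmax cross-entropy, and an Adam
optimizer with decoupled weight decay.  Gradients are accumulated by
topological traversal of the recorded op graph.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    # ---- graph traversal -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)
        out._backward = bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)
        out._backward = bw
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.data / other.data**2, other.shape)
        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        """``self @ other`` with ``other`` 2-D; self may have leading dims."""
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                a = self.data.reshape(-1, self.data.shape[-1])
                gg = g.reshape(-1, g.shape[-1])
                other.grad += a.T @ gg
        out._backward = bw
        return out

    # ---- reductions & shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self.grad += np.broadcast_to(gg, self.shape)
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), parents=(self,))

        def bw(g):
            self.grad += g * 0.5 / np.sqrt(self.data)
        out._backward = bw
        return out

    def max(self, axis: int):
        """Max-reduce along ``axis``; gradient routes to the argmax entries."""
        arg = self.data.argmax(axis=axis)
        out = Tensor(np.take_along_axis(self.data, np.expand_dims(arg, axis),
                                        axis=axis).squeeze(axis), parents=(self,))

        def bw(g):
            buf = np.zeros_like(self.data)
            np.put_along_axis(buf, np.expand_dims(arg, axis),
                              np.expand_dims(g, axis), axis=axis)
            self.grad += buf
        out._backward = bw
        return out

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """``self[index]`` for a 2-D tensor; index may be any integer shape."""
        out = Tensor(self.data[index], parents=(self,))

        def bw(g):
            np.add.at(self.grad, index.ravel(),
                      g.reshape(-1, g.shape[-1]))
        out._backward = bw
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t.grad += piece
    out._backward = bw
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, slope * x.data), parents=(x,))

    def bw(g):
        x.grad += g * np.where(pos, 1.0, slope)
    out._backward = bw
    return out


def cross_entropy(logits: Tensor, target: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Mean softmax cross-entropy over rows of an (N, C) logit tensor."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = len(target)
    w = np.ones(n) if class_weights is None else np.asarray(class_weights)[target]
    wsum = w.sum()
    loss = -(w * logp[np.arange(n), target]).sum() / wsum
    out = Tensor(loss, parents=(logits,))

    def bw(g):
        p = np.exp(logp)
        p[np.arange(n), target] -= 1.0
        logits.grad += g * p * (w / wsum)[:, None]
    out._backward = bw
    return out


def segment_max(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Per-segment max over rows of (N, C); returns (n_segments, C).

    Used for per-cloud global max pooling when several clouds are stacked in
    one batch.
    """
    N, C = x.data.shape
    arg = np.full((n_segments, C), -1, dtype=np.int64)
    val = np.full((n_segments, C), -np.inf)
    for s in range(n_segments):
        rows = np.nonzero(segment_ids == s)[0]
        sub = x.data[rows]
        a = sub.argmax(axis=0)
        arg[s] = rows[a]
        val[s] = sub[a, np.arange(C)]
    out = Tensor(val, parents=(x,))

    def bw(g):
        np.add.at(x.grad, (arg.ravel(), np.tile(np.arange(C), n_segments)), g.ravel())
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def set_training(self, flag: bool):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag

    # ---- flat (de)serialization ----
    def state_arrays(self, prefix: str = "") -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                out[prefix + k] = v.data
            elif isinstance(v, np.ndarray):
                out[prefix + k] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{prefix}{k}.{i}."))
        return out

    def load_state_arrays(self, state: dict, prefix: str = ""):
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                v.data = np.asarray(state[prefix + k], dtype=np.float64)
            elif isinstance(v, np.ndarray):
                setattr(self, k, np.asarray(state[prefix + k], dtype=np.float64))
            elif isinstance(v, Module):
                v.load_state_arrays(state, prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, f"{prefix}{k}.{i}.")


class Linear(Module):
    """Pointwise (1x1 convolution) linear map on the last axis."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, scale, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x.matmul(self.weight)
        return out + self.bias if self.bias is not None else out


class BatchNorm(Module):
    """Batch normalization over rows of (N, C) with running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = xc / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps))
        return self.gamma * xhat + self.beta


class Adam:
    """Adam with decoupled weight decay (decay applied to the raw weights)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
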