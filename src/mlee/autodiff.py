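"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to train the small encoder, the recurrent tagging heads
and the CRF losses: broadcast-aware elementwise ops, matmul, gather/scatter,
softmax / log-sum-exp, layer normalization, and an Adam optimizer.  Float64
throughout — the model is tiny, and exact reproducibility across runs matters
more than speed here.

Not a general framework: no in-place ops, no higher-order gradients.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        # Stealing g (no copy) is safe: all accumulations into a node happen
        # before its own backward_fn runs, and no op hands the same buffer to
        # two parents (__add__ copies for its second parent when needed).
        if self.grad is None:
            self.grad = g
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS: graphs from RNN/CRF loops run deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node.parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                go = _unbroadcast(g, other.data.shape)
                if go is g and self.requires_grad:
                    go = g.copy()  # never hand one buffer to two parents
                other._accum(go)

        out.backward_fn = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, (self,))
        out.backward_fn = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out.backward_fn = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out.backward_fn = bw
        return out

    # ------------------------------------------------------------ elementwise
    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out.backward_fn = lambda g: self.requires_grad and self._accum(g * (1 - y * y))
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, (self,))
        out.backward_fn = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def relu(self) -> "Tensor":
        pos = self.data > 0
        out = Tensor(self.data * pos, (self,))
        out.backward_fn = lambda g: self.requires_grad and self._accum(g * pos)
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out.backward_fn = bw
        return out

    def logsumexp(self, axis: int = -1, keepdims: bool = False) -> "Tensor":
        m = np.max(self.data, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        lse = np.log(s) + m
        soft = e / s
        out = Tensor(lse if keepdims else np.squeeze(lse, axis=axis), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g * soft)

        out.backward_fn = bw
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        m = np.max(self.data, axis=axis, keepdims=True)
        e = np.exp(self.data - np.where(np.isfinite(m), m, 0.0))
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        out.backward_fn = bw
        return out

    def layernorm(self, eps: float = 1e-5) -> "Tensor":
        """Normalize the last axis to zero mean, unit variance."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        out = Tensor(y, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            n = self.data.shape[-1]
            gy = g * inv
            self._accum(
                gy
                - gy.mean(axis=-1, keepdims=True)
                - y * (gy * y).mean(axis=-1, keepdims=True)
            )

        out.backward_fn = bw
        return out

    # ----------------------------------------------------------- shape & index
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), (self,))
        out.backward_fn = (
            lambda g: self.requires_grad and self._accum(g.reshape(self.data.shape))
        )
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), (self,))
        out.backward_fn = (
            lambda g: self.requires_grad and self._accum(np.swapaxes(g, a, b))
        )
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], (self,))
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, np.integer, slice)) for p in parts)

        def bw(g):
            if not self.requires_grad:
                return
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            if basic:  # no repeated positions: plain slice accumulation
                self.grad[idx] += g
            else:
                np.add.at(self.grad, idx, g)

        out.backward_fn = bw
        return out

    def masked_fill(self, mask: np.ndarray, value: float) -> "Tensor":
        """Where ``mask`` is True, replace entries with ``value`` (no gradient
        flows through the filled entries)."""
        mask = np.broadcast_to(mask, self.data.shape)
        out = Tensor(np.where(mask, value, self.data), (self,))
        out.backward_fn = (
            lambda g: self.requires_grad and self._accum(np.where(mask, 0.0, g))
        )
        return out

    def where_static(self, cond: np.ndarray, other: "Tensor") -> "Tensor":
        """Elementwise select: ``cond ? self : other`` with a constant mask."""
        cond = np.broadcast_to(cond, self.data.shape)
        out = Tensor(np.where(cond, self.data, other.data), (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(np.where(cond, g, 0.0))
            if other.requires_grad:
                other._accum(_unbroadcast(np.where(cond, 0.0, g), other.data.shape))

        out.backward_fn = bw
        return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rate`` is 0 or ``rng`` is None
    (inference)."""
    if rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * keep


def crf_forward_step(alpha: Tensor, trans: Tensor) -> Tensor:
    """One step of the CRF forward recursion, fused into a single node:

        out[b, j] = logsumexp_i(alpha[b, i] + trans[i, j])

    Equivalent to ``(alpha[:, :, None] + trans[None]).logsumexp(axis=1)`` but
    avoids materializing intermediate graph nodes in the hot loop.
    """
    A = alpha.data[:, :, None] + trans.data[None, :, :]
    m = A.max(axis=1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(A - m)
    s = e.sum(axis=1, keepdims=True)
    soft = e / s
    out = Tensor(np.log(s[:, 0, :]) + m[:, 0, :], (alpha, trans))

    def bw(g):
        w = soft * g[:, None, :]
        if alpha.requires_grad:
            alpha._accum(w.sum(axis=2))
        if trans.requires_grad:
            trans._accum(w.sum(axis=0))

    out.backward_fn = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out.backward_fn = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out.backward_fn = bw
    return out


class Adam:
    """Adam with bias correction; deterministic given the update sequence."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = 5.0,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.clip_norm = lr, betas, eps, clip_norm
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float((p.grad ** 2).sum()) for p in self.params if p.grad is not None)
            )
            scale = self.clip_norm / total if total > self.clip_norm else 1.0
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
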