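"""Minimal reverse-mode automatic differentiation over numpy arrays.

The score network needs exactly one capability no installed library
provides: gradients of a convolutional network's loss with respect to its
weights.  This module supplies it with a small, dependency-free tape: a
:class:`Tensor` wraps an ``ndarray`` and records the backward closure of
the op that produced it; :meth:`Tensor.backward` runs the tape in reverse
topological order.

Only the ops the U-Net uses are implemented — elementwise arithmetic with
numpy broadcasting, matmul, SiLU/ReLU/sigmoid, reductions, reshape/concat/
crop, same-padding odd-kernel convolution, fused group normalization, 2x
average pooling and nearest upsampling.  Spatial tensors are channels-last
(NHWC) and convolutions run as a single im2col + BLAS sgemm per pass,
which is what makes CPU training practical; Python scalars stay weakly
typed so float32 graphs remain float32 end to end (gradient-check tests
run the same ops in float64).
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "conv2d", "avg_pool2", "upsample2", "crop2d",
           "group_norm", "transpose_nchw"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the tape entry needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents: Tuple[Tensor, ...] = tuple(_parents)
        self._backward = _backward

    # -- introspection -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    # -- autograd driver -----------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the recorded tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: List[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        # python scalars stay weakly typed so float32 graphs remain float32
        if isinstance(other, (int, float)):
            out = Tensor(self.data + other, _parents=(self,))

            def bwd_s(g):
                if self.requires_grad:
                    self._accum(g)

            out._backward = bwd_s
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, _parents=(self,))

            def bwd_s(g):
                if self.requires_grad:
                    self._accum(g * other)

            out._backward = bwd_s
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        return self * (Tensor._lift(other) ** -1.0)

    def __rtruediv__(self, other):
        return Tensor._lift(other) * (self**-1.0)

    def __pow__(self, e: float):
        e = float(e)
        out = Tensor(self.data**e, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        out._backward = bwd
        return out

    # -- nonlinearities --------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bwd
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = bwd
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 + self.data * (1.0 - s)))

        out._backward = bwd
        return out

    # -- reductions and reshapes -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bwd
        return out


# -- structural ops ------------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` (used for U-Net skip connections)."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def crop2d(x: Tensor, h: int, w: int) -> Tensor:
    """Crop the spatial dims (axes 1, 2 of NHWC) to ``(h, w)`` (adjoint: zero-pad)."""
    out = Tensor(x.data[:, :h, :w], _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, :h, :w] = g
            x._accum(full)

    out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Same-padding stride-1 2-D convolution in channels-last layout.

    ``x``: (B, H, W, Cin); ``w``: (k, k, Cin, Cout) with odd ``k``;
    ``b``: (Cout,) or None.  Channels-last keeps the im2col buffer and
    the single sgemm per pass contiguous, which is what makes CPU
    training viable.
    """
    B, H, W, Cin = x.data.shape
    k, k2, Cin_w, Cout = w.data.shape
    if Cin != Cin_w or k != k2 or k % 2 == 0:
        raise ValueError(f"bad conv shapes x={x.data.shape} w={w.data.shape}")
    p = k // 2
    bhw = B * H * W
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0)))
    # im2col via one contiguous copy of the sliding-window view: (B*H*W, k*k*Cin)
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # view: (B, H, W, Cin, k, k) -> order taps-major, channel-minor
    cols = np.ascontiguousarray(view.transpose(0, 1, 2, 4, 5, 3)).reshape(bhw, k * k * Cin)
    w2 = w.data.reshape(k * k * Cin, Cout)
    out_data = (cols @ w2).reshape(B, H, W, Cout)
    if b is not None:
        out_data += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def bwd(g):
        g2 = np.ascontiguousarray(g).reshape(bhw, Cout)
        if x.requires_grad:
            dcols = (g2 @ w2.T).reshape(B, H, W, k, k, Cin)
            gxp = np.zeros_like(xp)
            for u in range(k):
                for v in range(k):
                    gxp[:, u : u + H, v : v + W, :] += dcols[:, :, :, u, v, :]
            x._accum(gxp[:, p : p + H, p : p + W, :])
        if w.requires_grad:
            w._accum((cols.T @ g2).reshape(k, k, Cin, Cout))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))

    out._backward = bwd
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling on NHWC; spatial dims must be even."""
    B, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {(H, W)}")
    out = Tensor(
        x.data.reshape(B, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4)), _parents=(x,)
    )

    def bwd(g):
        if x.requires_grad:
            gg = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25
            x._accum(gg)

    out._backward = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling on NHWC."""
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2), _parents=(x,))
    B, H, W, C = x.data.shape

    def bwd(g):
        if x.requires_grad:
            x._accum(g.reshape(B, H, 2, W, 2, C).sum(axis=(2, 4)))

    out._backward = bwd
    return out


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """Fused group normalization over an NHWC tensor.

    Normalizes each (sample, channel-group) slab to zero mean / unit
    variance, then applies per-channel scale and shift.  Fused into one
    op (forward and analytic backward) because the composed-primitive
    version dominates the network's runtime.
    """
    B, H, W, C = x.data.shape
    G = groups
    Cg = C // G
    if C % G:
        raise ValueError(f"channels {C} not divisible by groups {G}")
    n = H * W * Cg
    x2 = x.data.reshape(B, H * W, C)

    def _group_stat(a2: np.ndarray) -> np.ndarray:
        # (B, HW, C) -> per-(sample, group) sum, expanded back to (B, 1, C);
        # reduce over the middle axis keeps the contiguous C axis vectorized
        s = a2.sum(axis=1).reshape(B, G, Cg).sum(axis=2)
        return np.repeat(s, Cg, axis=1)[:, None, :]

    mu = _group_stat(x2) / n
    ex2 = _group_stat(x2 * x2) / n
    inv = 1.0 / np.sqrt(ex2 - mu * mu + eps)
    xn = (x2 - mu) * inv
    out_data = (xn * gamma.data + beta.data).reshape(B, H, W, C)
    out = Tensor(out_data, _parents=(x, gamma, beta))

    def bwd(g):
        g2 = g.reshape(B, H * W, C)
        if gamma.requires_grad:
            gamma._accum((g2 * xn).sum(axis=(0, 1)))
        if beta.requires_grad:
            beta._accum(g2.sum(axis=(0, 1)))
        if x.requires_grad:
            dxn = g2 * gamma.data
            s1 = _group_stat(dxn)
            s2 = _group_stat(dxn * xn)
            dx = inv * (dxn - (s1 + xn * s2) / n)
            x._accum(dx.reshape(B, H, W, C))

    out._backward = bwd
    return out


def transpose_nchw(x: Tensor) -> Tensor:
    """Reorder an NHWC tensor to NCHW (the package's external layout)."""
    out = Tensor(np.ascontiguousarray(x.data.transpose(0, 3, 1, 2)), _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(np.ascontiguousarray(g.transpose(0, 2, 3, 1)))

    out._backward = bwd
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 2e-4,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        grad_clip: Optional[float] = None,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.grad_clip is not None:
            gnorm = float(np.sqrt(sum(float((g**2).sum()) for g in grads)))
            if gnorm > self.grad_clip:
                scale = self.grad_clip / (gnorm + 1e-12)
                grads = [g * scale for g in grads]
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
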