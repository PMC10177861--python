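"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the dense denoising network and its
composite loss need: broadcast arithmetic, ReLU, channel concatenation,
3x3/1x1 convolutions (im2col + matmul), batch normalisation, Gaussian
blurring (self-adjoint under zero padding), reductions, log and abs.
Gradients are accumulated by reverse topological sweep; correctness is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = ["Tensor", "concat", "relu", "conv2d", "conv1x1", "batchnorm2d",
           "gaussian_blur", "maximum_scalar", "log", "absolute"]


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph machinery ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
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
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, grad):
        self.grad = grad if self.grad is None else self.grad + grad

    # -- helpers ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g) if self.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2,
                                               other.data.shape))
        out._backward = back
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))
        out._backward = back
        return out

    # -- reductions ---------------------------------------------------------
    def mean(self):
        out = Tensor(self.data.mean(), parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, g / self.data.size))
        out._backward = back
        return out

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, g))
        out._backward = back
        return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum a broadcast gradient back down to the original operand shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def relu(x: Tensor) -> Tensor:
    x = astensor(x)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * mask)
    out._backward = back
    return out


def log(x: Tensor) -> Tensor:
    x = astensor(x)
    out = Tensor(np.log(x.data), parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g / x.data)
    out._backward = back
    return out


def absolute(x: Tensor) -> Tensor:
    x = astensor(x)
    out = Tensor(np.abs(x.data), parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * np.sign(x.data))
    out._backward = back
    return out


def maximum_scalar(x: Tensor, lo: float) -> Tensor:
    """Elementwise ``max(x, lo)``; gradient flows only where x > lo."""
    x = astensor(x)
    mask = x.data > lo
    out = Tensor(np.where(mask, x.data, lo), parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * mask)
    out._backward = back
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)
    out._backward = back
    return out


# ---------------------------------------------------------------------------
# convolutions

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*kh*kw) patches under same-padding."""
    N, C, H, W = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, C, H, W, kh, kw) -> (N, H, W, C, kh, kw)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * kh * kw)


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None) -> Tensor:
    """Same-padding stride-1 2-D convolution (cross-correlation).

    ``x``: (N, C_in, H, W); ``weight``: (C_out, C_in, kh, kw) with odd kh, kw;
    ``bias``: (C_out,).  Spatial dimensions are preserved.
    """
    x = astensor(x)
    weight = astensor(weight)
    N, C, H, W = x.data.shape
    Cout, Cin, kh, kw = weight.data.shape
    if Cin != C:
        raise ValueError("channel mismatch in conv2d")
    cols = _im2col(x.data, kh, kw)                       # (N*H*W, C*kh*kw)
    Wmat = weight.data.reshape(Cout, -1).T               # (C*kh*kw, Cout)
    y = (cols @ Wmat).reshape(N, H, W, Cout).transpose(0, 3, 1, 2)
    if bias is not None:
        y = y + astensor(bias).data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, astensor(bias))
    out = Tensor(y, parents=parents)

    def back(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(N * H * W, Cout)
        if weight.requires_grad:
            gw = (cols.T @ gmat).T.reshape(Cout, C, kh, kw)
            weight._accumulate(gw)
        if bias is not None and parents[2].requires_grad:
            parents[2]._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # grad wrt input = convolution of g with the flipped, transposed kernel
            wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, Cout, kh, kw)
            gcols = _im2col(g, kh, kw)
            gx = (gcols @ wflip.reshape(C, -1).T).reshape(N, H, W, C).transpose(0, 3, 1, 2)
            x._accumulate(gx)
    out._backward = back
    return out


def conv1x1(x: Tensor, weight: Tensor) -> Tensor:
    """Pointwise channel-mixing convolution; ``weight``: (C_out, C_in)."""
    x = astensor(x)
    weight = astensor(weight)
    y = np.einsum("oc,nchw->nohw", weight.data, x.data)
    out = Tensor(y, parents=(x, weight))

    def back(g):
        if weight.requires_grad:
            weight._accumulate(np.einsum("nohw,nchw->oc", g, x.data))
        if x.requires_grad:
            x._accumulate(np.einsum("oc,nohw->nchw", weight.data, g))
    out._backward = back
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running: Optional[dict] = None, training: bool = True,
                momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    In training mode the batch statistics are used and ``running`` (a dict
    with ``mean``/``var`` arrays) is updated in place; in eval mode the
    running statistics are used.
    """
    x = astensor(x)
    gamma = astensor(gamma)
    beta = astensor(beta)
    axes = (0, 2, 3)
    if training or running is None:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        if running is not None:
            running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
            running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(y, parents=(x, gamma, beta))
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    use_batch_stats = training or running is None

    def back(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gy = g * gamma.data[None, :, None, None]
            if use_batch_stats:
                gsum = gy.sum(axis=axes)
                gxhat = (gy * xhat).sum(axis=axes)
                gx = (inv[None, :, None, None] / m
                      * (m * gy
                         - gsum[None, :, None, None]
                         - xhat * gxhat[None, :, None, None]))
            else:
                gx = gy * inv[None, :, None, None]
            x._accumulate(gx)
    out._backward = back
    return out


def gaussian_blur(x: Tensor, sigma: float, truncate: float = 3.0) -> Tensor:
    """2-D Gaussian blur of the trailing two axes, zero-padded boundary.

    The kernel is symmetric and the boundary zero, so the operator is
    self-adjoint: the backward pass is the same blur applied to the incoming
    gradient.
    """
    x = astensor(x)

    def blur(a):
        return ndimage.gaussian_filter(
            a, sigma=[0] * (a.ndim - 2) + [sigma, sigma],
            mode="constant", cval=0.0, truncate=truncate)

    out = Tensor(blur(x.data), parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(blur(g))
    out._backward = back
    return out
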