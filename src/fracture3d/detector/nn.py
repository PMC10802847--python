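"""Minimal reverse-mode autodiff over NumPy arrays, NCHW layout.

Just enough machinery for a one-stage convolutional detector: 2D
convolution, batch normalization, mish activation, stride-1 max pooling,
nearest-neighbour upsampling, concatenation, reshape/slice plumbing and
fused, numerically stable losses, with an Adam optimizer.  Gradients flow
through a recorded tape (topological order), micrograd-style but
vectorized.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = lambda: None
        self._prev = _prev
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            node._backward()

    def item(self) -> float:
        return float(self.data)


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._prev for t in tensors)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _prev=(a, b))

    def _backward():
        a._accumulate(out.grad)
        b._accumulate(out.grad)

    out._backward = _backward
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, _prev=(a,))

    def _backward():
        a._accumulate(out.grad * s)

    out._backward = _backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), _prev=(a,))

    def _backward():
        a._accumulate(out.grad.reshape(a.data.shape))

    out._backward = _backward
    return out


def slice_axis(a: Tensor, axis: int, start: int, stop: int) -> Tensor:
    index = [slice(None)] * a.data.ndim
    index[axis] = slice(start, stop)
    index = tuple(index)
    out = Tensor(a.data[index], _prev=(a,))

    def _backward():
        g = np.zeros_like(a.data)
        g[index] = out.grad
        a._accumulate(g)

    out._backward = _backward
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward():
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * out.grad.ndim
            index[axis] = slice(o0, o1)
            t._accumulate(out.grad[tuple(index)])

    out._backward = _backward
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2D convolution, NCHW input, weight (F, C, kh, kw)."""
    n, c, h, wd = x.data.shape
    f, c2, kh, kw = w.data.shape
    assert c == c2, f"channel mismatch {c} vs {c2}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (wd + 2 * pad - kw) // stride + 1
    out_data = np.zeros((n, f, oh, ow), dtype=np.float32)
    # accumulate one kernel tap at a time: each tap is a (C -> F) matmul
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
            out_data += np.einsum("nchw,fc->nfhw", xs, w.data[:, :, i, j], optimize=True)
    if b is not None:
        out_data += b.data[None, :, None, None]
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def _backward():
        g = out.grad
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
                dw[:, :, i, j] = np.einsum("nfhw,nchw->fc", g, xs, optimize=True)
                dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += np.einsum(
                    "nfhw,fc->nchw", g, w.data[:, :, i, j], optimize=True
                )
        w._accumulate(dw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if pad:
            x._accumulate(dxp[:, :, pad:-pad, pad:-pad])
        else:
            x._accumulate(dxp)

    out._backward = _backward
    return out


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    train: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    if train:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = Tensor(
        gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None],
        _prev=(x, gamma, beta),
    )

    def _backward():
        g = out.grad
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        m = g.shape[0] * g.shape[2] * g.shape[3]
        gxhat = g * gamma.data[None, :, None, None]
        if train:
            # full batch-norm backward through the batch statistics
            dx = (
                gxhat
                - gxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
            ) * inv_std[None, :, None, None]
        else:
            dx = gxhat * inv_std[None, :, None, None]
        x._accumulate(dx)

    out._backward = _backward
    return out


def mish(x: Tensor) -> Tensor:
    """x * tanh(softplus(x)) — the smooth activation used in the backbone."""
    sp = np.logaddexp(0.0, x.data)  # stable softplus
    t = np.tanh(sp)
    out = Tensor(x.data * t, _prev=(x,))

    def _backward():
        sig = 1.0 / (1.0 + np.exp(-x.data))
        grad = t + x.data * sig * (1.0 - t * t)
        x._accumulate(out.grad * grad)

    out._backward = _backward
    return out


def maxpool2d_same(x: Tensor, kernel: int) -> Tensor:
    """Stride-1 max pooling with same-size output (for SPP)."""
    pad = kernel // 2
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    best = np.full((n, c, h, w), -np.inf, dtype=np.float32)
    argmax = np.zeros((n, c, h, w), dtype=np.int16)
    for idx, (i, j) in enumerate((i, j) for i in range(kernel) for j in range(kernel)):
        window = xp[:, :, i : i + h, j : j + w]
        better = window > best
        best[better] = window[better]
        argmax[better] = idx
    out = Tensor(best, _prev=(x,))

    def _backward():
        dxp = np.zeros_like(xp)
        for idx, (i, j) in enumerate((i, j) for i in range(kernel) for j in range(kernel)):
            sel = argmax == idx
            dxp[:, :, i : i + h, j : j + w][sel] += out.grad[sel]
        x._accumulate(dxp[:, :, pad : pad + h, pad : pad + w])

    out._backward = _backward
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), _prev=(x,))

    def _backward():
        g = out.grad
        n, c, h2, w2 = g.shape
        x._accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    out._backward = _backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _prev=(x,))

    def _backward():
        x._accumulate(out.grad * s * (1.0 - s))

    out._backward = _backward
    return out


def bce_with_logits(x: Tensor, target: np.ndarray, weight: np.ndarray | float = 1.0) -> Tensor:
    """Weighted binary cross-entropy on logits, summed then batch-averaged."""
    n = x.data.shape[0] if x.data.ndim else 1
    sp = np.logaddexp(0.0, x.data)
    loss = weight * (sp - x.data * target)
    out = Tensor(loss.sum() / n, _prev=(x,))

    def _backward():
        sig = 1.0 / (1.0 + np.exp(-x.data))
        x._accumulate(out.grad * weight * (sig - target) / n)

    out._backward = _backward
    return out


def mse_weighted(x: Tensor, target: np.ndarray, weight: np.ndarray | float = 1.0) -> Tensor:
    """Weighted squared error, summed then batch-averaged."""
    n = x.data.shape[0] if x.data.ndim else 1
    diff = x.data - target
    out = Tensor((weight * diff * diff).sum() / n, _prev=(x,))

    def _backward():
        x._accumulate(out.grad * 2.0 * weight * diff / n)

    out._backward = _backward
    return out


class Adam:
    """Adaptive moment estimation over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
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
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
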