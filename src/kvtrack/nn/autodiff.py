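"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations the tracking networks need are provided: strided
convolution and transposed convolution (via im2col/col2im and BLAS
matmuls), pointwise activations, concatenation, means, absolute value and
logarithms.  Gradients are exact (verified against finite differences in
the test suite); everything runs in float64 on the CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "conv_transpose2d", "leaky_relu", "relu", "sigmoid",
           "concat", "mean", "abs_", "log", "clip_eps", "add", "sub", "scale",
           "instance_norm"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the graph
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in t._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # small conveniences used by the training loop
    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# im2col / col2im plumbing


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # n, c, ho, wo, k, k
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * k * k
    )
    return cols, ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    d6 = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, c, hp, wp))
    for a in range(k):
        for b in range(k):
            dxp[:, :, a : a + ho * stride : stride, b : b + wo * stride : stride] += d6[
                :, :, :, :, a, b
            ]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


def _conv_fwd(x, w, stride, pad):
    f, c, k, _ = w.shape
    cols, ho, wo = _im2col(x, k, stride, pad)
    out = cols @ w.reshape(f, c * k * k).T
    return out.reshape(x.shape[0], ho, wo, f).transpose(0, 3, 1, 2), cols


def _conv_dx(dout, w, x_shape, stride, pad):
    f, c, k, _ = w.shape
    dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, f)
    dcols = dmat @ w.reshape(f, c * k * k)
    return _col2im(dcols, x_shape, k, stride, pad)


def _conv_dw(dout, cols, w_shape):
    f, c, k, _ = w_shape
    dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, f)
    return (dmat.T @ cols).reshape(f, c, k, k)


# ---------------------------------------------------------------------------
# autodiff operations


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2D cross-correlation; w has shape (out_ch, in_ch, k, k)."""
    out, cols = _conv_fwd(x.data, w.data, stride, pad)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(g):
        grads = [
            (x, _conv_dx(g, w.data, x.data.shape, stride, pad)),
            (w, _conv_dw(g, cols, w.data.shape)),
        ]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return grads

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2, pad: int = 1) -> Tensor:
    """Transposed convolution; w has shape (in_ch, out_ch, k, k).

    The forward pass is the adjoint of :func:`conv2d`: output spatial size
    is ``(H - 1) * stride - 2 * pad + k``.
    """
    cin, cout, k, _ = w.data.shape
    n, _, h, wdt = x.data.shape
    ho = (h - 1) * stride - 2 * pad + k
    wo = (wdt - 1) * stride - 2 * pad + k
    out_shape = (n, cout, ho, wo)
    out = _conv_dx(x.data, w.data, out_shape, stride, pad)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(g):
        # dx: forward conv of g with the same kernel
        dx, cols_g = _conv_fwd(g, w.data, stride, pad)
        dw = _conv_dw(x.data, cols_g, w.data.shape)
        grads = [(x, dx), (w, dw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return grads

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=backward)


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    pos = x.data > 0
    out = np.where(pos, x.data, alpha * x.data)
    return Tensor(out, parents=(x,), backward=lambda g: [(x, np.where(pos, g, alpha * g))])


def relu(x: Tensor) -> Tensor:
    return leaky_relu(x, 0.0)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(s, parents=(x,), backward=lambda g: [(x, g * s * (1.0 - s))])


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    na = a.data.shape[axis]
    out = np.concatenate([a.data, b.data], axis=axis)

    def backward(g):
        ga, gb = np.split(g, [na], axis=axis)
        return [(a, ga), (b, gb)]

    return Tensor(out, parents=(a, b), backward=backward)


def mean(x: Tensor) -> Tensor:
    n = x.data.size
    return Tensor(
        x.data.mean(), parents=(x,), backward=lambda g: [(x, np.full_like(x.data, g / n))]
    )


def abs_(x: Tensor) -> Tensor:
    s = np.sign(x.data)
    return Tensor(np.abs(x.data), parents=(x,), backward=lambda g: [(x, g * s)])


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.data), parents=(x,), backward=lambda g: [(x, g / x.data)])


def clip_eps(x: Tensor, eps: float) -> Tensor:
    """Clamp to [eps, 1 - eps]; gradient passes only through the interior."""
    out = np.clip(x.data, eps, 1.0 - eps)
    interior = (x.data > eps) & (x.data < 1.0 - eps)
    return Tensor(out, parents=(x,), backward=lambda g: [(x, np.where(interior, g, 0.0))])


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data + b.data, parents=(a, b), backward=lambda g: [(a, g), (b, g)])


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data - b.data, parents=(a, b), backward=lambda g: [(a, g), (b, -g)])


def scale(x: Tensor, c: float) -> Tensor:
    return Tensor(c * x.data, parents=(x,), backward=lambda g: [(x, c * g)])


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over the spatial axes."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        m = x.data.shape[2] * x.data.shape[3]
        gg = g * gamma.data[None, :, None, None]
        gmean = gg.mean(axis=(2, 3), keepdims=True)
        gxhat = (gg * xhat).mean(axis=(2, 3), keepdims=True)
        dx = inv * (gg - gmean - xhat * gxhat)
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        return [(x, dx), (gamma, dgamma), (beta, dbeta)]

    return Tensor(out, parents=(x, gamma, beta), backward=backward)
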