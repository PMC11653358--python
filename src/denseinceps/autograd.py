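"""Compact reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the fused CNN needs: (grouped)
convolution, batch normalization, ReLU, max/average pooling, channel
concatenation, reshape, matrix products, softmax and the combined
softmax-cross-entropy loss.  Tensors carry float32 data in NCHW layout
for image-shaped values.

The engine is tape-based: every op records a backward closure on its
output tensor; ``Tensor.backward()`` topologically sorts the graph and
accumulates gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "batch_norm",
    "relu",
    "max_pool2d",
    "global_avg_pool",
    "concat",
    "reshape",
    "matmul",
    "add",
    "mean",
    "softmax",
    "linear",
    "softmax_cross_entropy",
]


class Tensor:
    """A NumPy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False, _prev=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None


def _out(data, parents, backward, requires_grad=None):
    if requires_grad is None:
        requires_grad = any(p.requires_grad for p in parents)
    t = Tensor(data, requires_grad=requires_grad,
               _prev=[p for p in parents if p.requires_grad])
    if requires_grad:
        t._backward = backward
    return t


# ---------------------------------------------------------------------------
# elementwise / shape ops


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * mask)

    return _out(x.data * mask, [x], backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    return _out(a.data + b.data, [a, b], backward)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape

    def backward(g):
        x._accumulate(g.reshape(old))

    return _out(x.data.reshape(shape), [x], backward)


def concat(xs, axis=1) -> Tensor:
    sizes = [t.data.shape[axis] for t in xs]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, gi in zip(xs, np.split(g, splits, axis=axis)):
            t._accumulate(gi)

    return _out(np.concatenate([t.data for t in xs], axis=axis), list(xs), backward)


def mean(x: Tensor, axis, keepdims=False) -> Tensor:
    axes = axis if isinstance(axis, tuple) else (axis,)
    n = 1
    for a in axes:
        n *= x.data.shape[a]

    def backward(g):
        gg = g if keepdims else np.expand_dims(g, axes)
        x._accumulate(np.broadcast_to(gg / n, x.data.shape))

    return _out(x.data.mean(axis=axis, keepdims=keepdims), [x], backward)


# ---------------------------------------------------------------------------
# dense algebra


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with NumPy broadcasting over leading axes."""

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _out(a.data @ b.data, [a, b], backward)


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (..., din) @ w (din, dout) + b."""
    out = x.data @ w.data
    if b is not None:
        out = out + b.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(_unbroadcast(g @ w.data.T, x.data.shape))
        if w.requires_grad:
            gw = np.swapaxes(x.data, -1, -2) @ g
            w._accumulate(_unbroadcast(gw, w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))

    parents = [x, w] + ([b] if b is not None else [])
    return _out(out, parents, backward)


def softmax(x: Tensor, axis=-1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return _out(s, [x], backward)


def softmax_cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean of -t_y + log(sum_j exp(t_j)) over the batch (log-sum-exp stable)."""
    z = logits.data.astype(np.float64)
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    n = z.shape[0]
    idx = np.arange(n)
    losses = lse - z[idx, y]

    def backward(g):
        p = np.exp(z - lse[:, None])
        p[idx, y] -= 1.0
        logits._accumulate((g * p / n).astype(np.float32))

    return _out(losses.mean(), [logits], backward)


# ---------------------------------------------------------------------------
# convolution / pooling

_SAME, _VALID = "same", "valid"


def _pad_amount(size, f, stride, padding):
    if padding == _SAME:
        if stride != 1:
            raise ValueError("same-padding only supported for stride 1")
        total = f - 1
        return total // 2, total - total // 2
    return 0, 0


def conv_out_size(size, f, stride, padding):
    lo, hi = _pad_amount(size, f, stride, padding)
    return (size + lo + hi - f) // stride + 1


def _window_view(xp, fh, fw, stride):
    # (N, C, Ho, Wo, fh, fw) strided view of the padded input
    from numpy.lib.stride_tricks import sliding_window_view

    v = sliding_window_view(xp, (fh, fw), axis=(2, 3))
    return v[:, :, ::stride, ::stride, :, :]


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride=1, padding=_VALID,
           groups=1) -> Tensor:
    """Grouped 2-D cross-correlation, NCHW; weights (Cout, Cin/groups, fh, fw)."""
    n, cin, h, wd = x.data.shape
    cout, cin_g, fh, fw = w.data.shape
    if cin % groups or cout % groups or cin_g != cin // groups:
        raise ValueError("channel counts incompatible with groups")
    plo_h, phi_h = _pad_amount(h, fh, stride, padding)
    plo_w, phi_w = _pad_amount(wd, fw, stride, padding)
    xp = x.data
    if plo_h or phi_h or plo_w or phi_w:
        xp = np.pad(xp, ((0, 0), (0, 0), (plo_h, phi_h), (plo_w, phi_w)))
    hp, wp = xp.shape[2], xp.shape[3]

    if fh == 1 and fw == 1 and groups == 1:
        # fast path: 1x1 convolution is a channel matmul
        xs = xp[:, :, ::stride, ::stride]
        ho, wo = xs.shape[2], xs.shape[3]
        out = np.einsum("nchw,dc->ndhw", xs, w.data[:, :, 0, 0],
                        optimize=True) + b.data[None, :, None, None]

        def backward(g):
            if w.requires_grad:
                w._accumulate(np.einsum("ndhw,nchw->dc", g, xs,
                                        optimize=True)[:, :, None, None])
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gx = np.einsum("ndhw,dc->nchw", g, w.data[:, :, 0, 0],
                               optimize=True)
                gfull = np.zeros((n, cin, hp, wp), dtype=np.float32)
                gfull[:, :, ::stride, ::stride] = gx
                x._accumulate(gfull[:, :, plo_h:hp - phi_h or None,
                                    plo_w:wp - phi_w or None])

        return _out(out, [x, w, b], backward)

    # im2col once (one contiguous copy), then per-group BLAS matmuls
    v = _window_view(xp, fh, fw, stride)  # (N,C,Ho,Wo,fh,fw)
    ho, wo = v.shape[2], v.shape[3]
    cg_in, cg_out = cin // groups, cout // groups
    cols = np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, groups, cg_in * fh * fw, ho * wo)
    wg = w.data.reshape(groups, cg_out, cg_in * fh * fw)
    out = np.matmul(wg[None], cols).reshape(n, cout, ho, wo) \
        + b.data[None, :, None, None]

    def backward(g):
        gg = g.reshape(n, groups, cg_out, ho * wo)
        if w.requires_grad:
            gw = np.matmul(gg, cols.transpose(0, 1, 3, 2)).sum(axis=0)
            w._accumulate(gw.reshape(cout, cg_in, fh, fw))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(wg.transpose(0, 2, 1)[None], gg)
            dcols = dcols.reshape(n, cin, fh, fw, ho, wo)
            gx = np.zeros((n, cin, hp, wp), dtype=np.float32)
            for i in range(fh):
                for j in range(fw):
                    gx[:, :, i:i + ho * stride:stride,
                       j:j + wo * stride:stride] += dcols[:, :, i, j]
            x._accumulate(gx[:, :, plo_h:hp - phi_h or None,
                             plo_w:wp - phi_w or None])

    return _out(out, [x, w, b], backward)


def max_pool2d(x: Tensor, f=3, stride=2, padding=_VALID) -> Tensor:
    n, c, h, wd = x.data.shape
    plo_h, phi_h = _pad_amount(h, f, stride, padding)
    plo_w, phi_w = _pad_amount(wd, f, stride, padding)
    xp = x.data
    if plo_h or phi_h or plo_w or phi_w:
        xp = np.pad(xp, ((0, 0), (0, 0), (plo_h, phi_h), (plo_w, phi_w)),
                    constant_values=-np.inf)
    hp, wp = xp.shape[2], xp.shape[3]
    v = _window_view(xp, f, f, stride)  # (N,C,Ho,Wo,f,f)
    ho, wo = v.shape[2], v.shape[3]
    flat = v.reshape(n, c, ho, wo, f * f)
    arg = flat.argmax(axis=4)
    out = np.take_along_axis(flat, arg[..., None], axis=4)[..., 0]

    def backward(g):
        gx = np.zeros((n, c, hp, wp), dtype=np.float32)
        ai, aj = np.unravel_index(arg, (f, f))
        for i in range(f):
            for j in range(f):
                m = (ai == i) & (aj == j)
                gx[:, :, i:i + ho * stride:stride,
                   j:j + wo * stride:stride] += g * m
        x._accumulate(gx[:, :, plo_h:hp - phi_h or None,
                         plo_w:wp - phi_w or None])

    return _out(out, [x], backward)


def global_avg_pool(x: Tensor) -> Tensor:
    return mean(x, axis=(2, 3), keepdims=True)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
               running_var, training: bool, momentum=0.1, eps=1e-5) -> Tensor:
    """Per-channel batch normalization over (N,H,W); updates running stats in place."""
    axes = (0, 2, 3) if x.data.ndim == 4 else (0,)
    shape = ((1, -1, 1, 1) if x.data.ndim == 4 else (1, -1))
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * inv.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    m = x.data.size // x.data.shape[1 if x.data.ndim == 4 else -1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gs = g * gamma.data.reshape(shape)
            if training:
                t1 = gs - gs.mean(axis=axes, keepdims=True)
                t2 = xhat * (gs * xhat).mean(axis=axes, keepdims=True)
                x._accumulate(inv.reshape(shape) * (t1 - t2))
            else:
                x._accumulate(gs * inv.reshape(shape))

    return _out(out, [x, gamma, beta], backward)
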