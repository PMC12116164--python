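"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports exactly the operations the segmentation network needs:
broadcast arithmetic, matmul, 2-D convolution (stride/padding/dilation),
batch normalisation, axis reductions, concatenation, bilinear upsampling,
sigmoid/relu and a pixel-wise softmax cross-entropy.  Gradients are
accumulated on `Tensor.grad` after calling `backward()` on a scalar loss.

Float dtype follows the input arrays: layers initialise parameters in
float32 for speed, while unit tests that hand-trace gradients can feed
float64 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "neg", "matmul", "relu", "sigmoid",
    "conv2d", "batchnorm2d", "mean", "amax", "concat", "narrow",
    "upsample_bilinear", "softmax_cross_entropy", "reshape",
]


def _as_array(x):
    if isinstance(x, np.ndarray):
        return x
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- array-ish sugar -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'none'})"

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    # -- graph machinery -------------------------------------------------
    def _accumulate(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce `grad` back to `shape` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- elementwise ---------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def sub(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data - b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(-_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def neg(a):
    a = _wrap(a)

    def backward(g):
        a._accumulate(-g)

    return _make(-a.data, (a,), backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def relu(a):
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a):
    a = _wrap(a)
    # numerically stable logistic: exp of a non-positive argument only
    e = np.exp(-np.abs(a.data))
    s = np.where(a.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e)).astype(a.dtype, copy=False)

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


# -- linear algebra ------------------------------------------------------

def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(data, (a, b), backward)


def reshape(a, shape):
    a = _wrap(a)
    old = a.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


# -- reductions ----------------------------------------------------------

def mean(a, axis=None, keepdims=False):
    a = _wrap(a)
    data = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])

    def backward(g):
        g = np.asarray(g)
        if not keepdims and axis is not None:
            g = np.expand_dims(g, axis=axis)
        a._accumulate(np.broadcast_to(g, a.shape) / n)

    return _make(data, (a,), backward)


def amax(a, axis=None, keepdims=False):
    """Max reduction; gradient is split uniformly among tied maxima."""
    a = _wrap(a)
    data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == data)
    counts = mask.sum(axis=axis, keepdims=True)
    out = data if keepdims else np.squeeze(data, axis=axis)

    def backward(g):
        g = np.asarray(g)
        if not keepdims and axis is not None:
            g = np.expand_dims(g, axis=axis)
        a._accumulate(np.broadcast_to(g, a.shape) * mask / counts)

    return _make(out, (a,), backward)


def narrow(a, axis, start, length):
    """Contiguous slice [start, start+length) along `axis`."""
    a = _wrap(a)
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accumulate(full)

    return _make(a.data[idx], (a,), backward)


def concat(tensors, axis=1):
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            t._accumulate(piece)

    return _make(data, tuple(tensors), backward)


# -- convolution ---------------------------------------------------------

def _conv_indices(h, w, kh, kw, stride, dilation, out_h, out_w):
    i0 = np.repeat(np.arange(kh) * dilation, kw)
    j0 = np.tile(np.arange(kw) * dilation, kh)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    i = i0[:, None] + i1[None, :]
    j = j0[:, None] + j1[None, :]
    return i, j


def conv2d(x, w, b=None, stride=1, padding=0, dilation=1):
    """NCHW 2-D convolution via im2col.

    x: (N,C,H,W); w: (O,C,kh,kw); b: (O,) or None.
    """
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    N, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    eff_h = (kh - 1) * dilation + 1
    eff_w = (kw - 1) * dilation + 1
    out_h = (H + 2 * padding - eff_h) // stride + 1
    out_w = (W + 2 * padding - eff_w) // stride + 1
    if out_h <= 0 or out_w <= 0:
        raise ValueError("conv2d output would be empty")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    i, j = _conv_indices(H, W, kh, kw, stride, dilation, out_h, out_w)
    cols = xp[:, :, i, j]                      # (N, C, kh*kw, L)
    L = out_h * out_w
    cols2 = cols.reshape(N, C * kh * kw, L)
    wf = w.data.reshape(O, -1)
    out = np.einsum("ok,nkl->nol", wf, cols2, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None]
    out = out.reshape(N, O, out_h, out_w)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gf = g.reshape(N, O, L)
        if b is not None:
            b._accumulate(gf.sum(axis=(0, 2)))
        w._accumulate(np.einsum("nol,nkl->ok", gf, cols2, optimize=True).reshape(w.shape))
        if x.requires_grad:
            dcols = np.einsum("ok,nol->nkl", wf, gf, optimize=True)
            dcols = dcols.reshape(N, C, kh * kw, L)
            dxp = np.zeros_like(xp)
            np.add.at(dxp, (slice(None), slice(None), i, j), dcols)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return _make(out, parents, backward)


# -- batch normalisation -------------------------------------------------

def batchnorm2d(x, gamma, beta, running_mean, running_var,
                training=True, momentum=0.1, eps=1e-5):
    """Per-channel batch normalisation on NCHW input.

    `running_mean`/`running_var` are plain numpy arrays updated in place
    during training (they carry no gradient).
    """
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mu = running_mean
        var = running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = g * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                term = gxh - gxh.mean(axis=(0, 2, 3), keepdims=True) \
                    - xhat * (gxh * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accumulate(term * inv[None, :, None, None])
            else:
                x._accumulate(gxh * inv[None, :, None, None])

    return _make(out, (x, gamma, beta), backward)


# -- resampling ----------------------------------------------------------

def upsample_bilinear(x, size):
    """Bilinear resize of NCHW input to `size` = (out_h, out_w).

    Uses the half-pixel (align_corners=False) convention.
    """
    x = _wrap(x)
    N, C, H, W = x.shape
    out_h, out_w = size
    if (out_h, out_w) == (H, W):
        return x

    def grid(n_in, n_out):
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        src = np.clip(src, 0, n_in - 1)
        lo = np.floor(src).astype(np.intp)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = src - lo
        return lo, hi, frac

    r0, r1, fr = grid(H, out_h)
    c0, c1, fc = grid(W, out_w)
    fr = fr[:, None]
    fc = fc[None, :]
    d = x.data
    top = d[:, :, r0, :][:, :, :, c0] * (1 - fc) + d[:, :, r0, :][:, :, :, c1] * fc
    bot = d[:, :, r1, :][:, :, :, c0] * (1 - fc) + d[:, :, r1, :][:, :, :, c1] * fc
    out = top * (1 - fr) + bot * fr

    def backward(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        w00 = (1 - fr) * (1 - fc)
        w01 = (1 - fr) * fc
        w10 = fr * (1 - fc)
        w11 = fr * fc
        rr0 = np.broadcast_to(r0[:, None], (out_h, out_w))
        rr1 = np.broadcast_to(r1[:, None], (out_h, out_w))
        cc0 = np.broadcast_to(c0[None, :], (out_h, out_w))
        cc1 = np.broadcast_to(c1[None, :], (out_h, out_w))
        np.add.at(dx, (slice(None), slice(None), rr0, cc0), g * w00)
        np.add.at(dx, (slice(None), slice(None), rr0, cc1), g * w01)
        np.add.at(dx, (slice(None), slice(None), rr1, cc0), g * w10)
        np.add.at(dx, (slice(None), slice(None), rr1, cc1), g * w11)
        x._accumulate(dx)

    return _make(out, (x,), backward)


# -- loss ----------------------------------------------------------------

def softmax_cross_entropy(logits, labels):
    """Mean pixel-wise cross-entropy.

    logits: (N, K, H, W) Tensor; labels: (N, H, W) integer array.
    """
    logits = _wrap(logits)
    labels = np.asarray(labels)
    N, K, H, W = logits.shape
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n_pix = N * H * W
    idx_n, idx_h, idx_w = np.meshgrid(np.arange(N), np.arange(H), np.arange(W), indexing="ij")
    logp = z - np.log(ez.sum(axis=1, keepdims=True))
    loss = -logp[idx_n, labels, idx_h, idx_w].mean()

    def backward(g):
        grad = p.copy()
        grad[idx_n, labels, idx_h, idx_w] -= 1.0
        logits._accumulate(g * grad / n_pix)

    return _make(np.asarray(loss), (logits,), backward)
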