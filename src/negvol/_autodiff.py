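"""A minimal tape-based reverse-mode autodiff engine on numpy arrays.

Supports exactly the operations the volumetric segmentation architectures
need: 3D convolution (stride 1 "same" or stride 2 "valid"), transposed
convolution (kernel = stride = 2), max pooling 2x2x2, ReLU, sigmoid, channel
concatenation, residual addition, channel tiling, broadcast multiplication,
softmax over channels, log, and reductions.  Tensors carry data of shape
``(C, D, H, W)`` (or scalars for losses); gradients are accumulated on a
topologically sorted tape.

This is intentionally a teaching-grade engine: float32 forward/backward,
no graph reuse, no in-place tricks.  It is fast enough for the scaled-down
phantom studies this package trains on.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = parents  # tuple of (Tensor, backward_fn(grad) -> grad_parent)
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p, _ in t.parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t.grad is None:
                continue
            for p, fn in t.parents:
                if p.requires_grad:
                    p._accumulate(fn(t.grad))

    # -- convenience scalar arithmetic (used by loss composition) ----------
    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data + other.data,
            parents=((self, lambda g: g), (other, lambda g: g)),
        )

    def __sub__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data - other.data,
            parents=((self, lambda g: g), (other, lambda g: -g)),
        )

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(
                (self, lambda g: g * other.data),
                (other, lambda g: g * self.data),
            ),
        )

    __rmul__ = __mul__
    __radd__ = __add__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data / other.data,
            parents=(
                (self, lambda g: g / other.data),
                (other, lambda g: -g * self.data / other.data**2),
            ),
        )


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=((x, lambda g: g * mask),))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -30, 30)))
    return Tensor(s, parents=((x, lambda g: g * s * (1 - s)),))


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.data), parents=((x, lambda g: g / x.data),))


def vsum(x: Tensor) -> Tensor:
    return Tensor(x.data.sum(), parents=((x, lambda g: np.broadcast_to(g, x.data.shape)),))


def concat(xs: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    sizes = [t.data.shape[0] for t in xs]
    bounds = np.cumsum([0] + sizes)

    def make_fn(i):
        return lambda g: g[bounds[i]: bounds[i + 1]]

    return Tensor(
        np.concatenate([t.data for t in xs], axis=0),
        parents=tuple((t, make_fn(i)) for i, t in enumerate(xs)),
    )


def tile_channels(x: Tensor, n: int) -> Tensor:
    """Repeat channels n times (residual input broadcast for 1-channel input)."""
    c = x.data.shape[0]
    return Tensor(
        np.tile(x.data, (n, 1, 1, 1)),
        parents=((x, lambda g: g.reshape((n, c) + g.shape[1:]).sum(axis=0)),),
    )


def mul_broadcast(x: Tensor, a: Tensor) -> Tensor:
    """x * a where a has a single channel broadcast over x's channels."""
    return Tensor(
        x.data * a.data,
        parents=(
            (x, lambda g: g * a.data),
            (a, lambda g: (g * x.data).sum(axis=0, keepdims=True)),
        ),
    )


def softmax_channels(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=0, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=0, keepdims=True)

    def back(g):
        dot = (g * p).sum(axis=0, keepdims=True)
        return p * (g - dot)

    return Tensor(p, parents=((x, back),))


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(C, D, H, W) -> (N_out_vox, C*k^3) plus output spatial shape."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
    win = win[:, ::stride, ::stride, ::stride]
    c, do, ho, wo = win.shape[:4]
    cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(do * ho * wo, c * k**3)
    return np.ascontiguousarray(cols), (do, ho, wo)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int, out_shape):
    """Adjoint of _im2col: scatter-add columns back to the input grid."""
    c, d, h, w = x_shape
    do, ho, wo = out_shape
    xp = np.zeros((c, d + 2 * pad, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    cols = cols.reshape(do, ho, wo, c, k, k, k).transpose(3, 0, 1, 2, 4, 5, 6)
    for a in range(k):
        for b in range(k):
            for cc in range(k):
                xp[
                    :,
                    a: a + stride * do: stride,
                    b: b + stride * ho: stride,
                    cc: cc + stride * wo: stride,
                ] += cols[:, :, :, :, a, b, cc]
    if pad:
        xp = xp[:, pad:-pad, pad:-pad, pad:-pad]
    return xp


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """3D convolution; stride 1 uses "same" zero padding (odd kernels),
    stride 2 with kernel 2 is the "valid" down-sampling convolution.

    w: (Cout, Cin, k, k, k); b: (Cout,).
    """
    cout, cin, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    pad = (k - 1) // 2 if stride == 1 else 0
    cols, out_sp = _im2col(x.data, k, stride, pad)
    wmat = w.data.reshape(cout, cin * k**3)
    out = cols @ wmat.T + b.data
    out = out.reshape(out_sp + (cout,)).transpose(3, 0, 1, 2)

    x_shape = x.data.shape

    def back_x(g):
        gmat = g.transpose(1, 2, 3, 0).reshape(-1, cout)
        return _col2im(gmat @ wmat, x_shape, k, stride, pad, out_sp)

    def back_w(g):
        gmat = g.transpose(1, 2, 3, 0).reshape(-1, cout)
        return (gmat.T @ cols).reshape(w.data.shape)

    def back_b(g):
        return g.sum(axis=(1, 2, 3))

    return Tensor(out, parents=((x, back_x), (w, back_w), (b, back_b)))


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Transposed convolution with kernel = stride = 2 (spatial doubling).

    w: (Cin, Cout, 2, 2, 2); b: (Cout,).
    """
    cin, cout = w.data.shape[0], w.data.shape[1]
    c, d, h, ww_ = x.data.shape
    # out[co, 2d+a, 2h+b_, 2w+c_] = sum_ci x[ci,d,h,w] * w[ci,co,a,b_,c_]
    t = np.tensordot(x.data, w.data, axes=([0], [0]))  # (d,h,w, cout,2,2,2)
    t = t.transpose(3, 0, 4, 1, 5, 2, 6).reshape(cout, 2 * d, 2 * h, 2 * ww_)
    t += b.data[:, None, None, None]

    def back_x(g):
        gr = g.reshape(cout, d, 2, h, 2, ww_, 2).transpose(1, 3, 5, 0, 2, 4, 6)
        return np.tensordot(gr, w.data, axes=([3, 4, 5, 6], [1, 2, 3, 4])).transpose(3, 0, 1, 2)

    def back_w(g):
        gr = g.reshape(cout, d, 2, h, 2, ww_, 2).transpose(1, 3, 5, 0, 2, 4, 6)
        return np.tensordot(x.data, gr, axes=([1, 2, 3], [0, 1, 2]))

    def back_b(g):
        return g.sum(axis=(1, 2, 3))

    return Tensor(t, parents=((x, back_x), (w, back_w), (b, back_b)))


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling (spatial halving)."""
    c, d, h, w = x.data.shape
    win = x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    win = win.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def back(g):
        gw = np.zeros(win.shape, dtype=np.float32)
        np.put_along_axis(gw, arg[..., None], g[..., None], axis=-1)
        gw = gw.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        gw = gw.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, d, h, w)
        return gw

    return Tensor(out, parents=((x, back),))


# ---------------------------------------------------------------------------
# parameters and optimizer
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> Parameter:
    return Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape))


class Adam:
    """Adam with decoupled-from-nothing L2 weight decay folded into the
    gradient (the convention of the reference deep-learning stack)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.99, eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.wd:
                g = g + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
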