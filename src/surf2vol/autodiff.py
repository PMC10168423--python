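"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable parts of the pipeline (3D convolutional generators, Wasserstein
critics and the refinement network) need gradients of scalar losses with
respect to network parameters, and — for the gradient penalty — gradients of
*those gradients*. Every primitive here therefore expresses its vector-Jacobian
products (VJPs) in terms of the same primitives, so a backward pass builds an
ordinary differentiable graph and arbitrary-order derivatives are available by
calling :func:`grad` repeatedly.

Only the operations the pipeline actually uses are provided: elementwise
arithmetic, reductions, ReLU/Tanh, matrix multiply, shape ops, and the three
convolution primitives (forward, transposed/adjoint, and weight-gradient),
which are closed under differentiation:

* ``d conv(x, w) / dx``  -> ``conv_transpose(g, w)``
* ``d conv(x, w) / dw``  -> ``conv_wgrad(x, g)``
* and the VJPs of those two are again ``conv``/``conv_transpose``/``conv_wgrad``.

Convolutions run in float32 over bounded depth slabs, dispatching between
direct numba kernels (plain or channel-blocked) and per-kernel-offset BLAS
products depending on the geometry.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "Tensor",
    "as_tensor",
    "constant",
    "parameter",
    "no_grad",
    "grad",
    "add",
    "sub",
    "mul",
    "neg",
    "div",
    "power",
    "sqrt",
    "absolute",
    "relu",
    "tanh",
    "sum_",
    "mean",
    "matmul",
    "transpose",
    "reshape",
    "broadcast_to",
    "concat",
    "slice_axis",
    "pad_axis",
    "conv3d",
    "conv_transpose3d",
    "conv3d_wgrad",
]

_GRAD_ENABLED = True

# direct numba kernels need output rows at least this long to vectorize well;
# shorter rows fall back to per-offset BLAS products
_NUMBA_MIN_W = 32
_NUMBA_MIN_W_GRAD = 32
# padded working copies for large convolutions are processed in depth slabs
# no bigger than this
_CHUNK_BYTES = 96 * 1024 * 1024


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / shape probes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus the recorded parents that produced it."""

    __slots__ = ("data", "parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.parents = tuple(parents)  # tuple of (Tensor, vjp callable)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    def __radd__(self, other):
        return add(as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    def __rmul__(self, other):
        return mul(as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32))


def constant(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float32))


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float32), requires_grad=True)


def _make(data, parents) -> Tensor:
    """Create a graph node; records only differentiable parents."""
    if _GRAD_ENABLED:
        kept = tuple((p, vjp) for p, vjp in parents if p.requires_grad)
        if kept:
            return Tensor(data, requires_grad=True, parents=kept)
    return Tensor(data)


# ---------------------------------------------------------------------------
# elementwise & reductions
# ---------------------------------------------------------------------------


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a gradient back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    ndim_extra = g.ndim - len(shape)
    axes = tuple(range(ndim_extra)) + tuple(
        i + ndim_extra for i, s in enumerate(shape) if s == 1 and g.shape[i + ndim_extra] != 1
    )
    out = sum_(g, axis=axes, keepdims=False) if axes else g
    return reshape(out, shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data + b.data,
        [
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(g, b.shape)),
        ],
    )


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data - b.data,
        [
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(neg(g), b.shape)),
        ],
    )


def neg(a: Tensor) -> Tensor:
    a = as_tensor(a)
    return _make(-a.data, [(a, lambda g: neg(g))])


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data * b.data,
        [
            (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
            (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
        ],
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    return mul(a, power(b, -1.0))


def power(a: Tensor, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    return _make(
        np.power(a.data, p, dtype=np.float32),
        [(a, lambda g: mul(g, mul(constant(p), power(a, p - 1.0))))],
    )


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def absolute(a: Tensor) -> Tensor:
    a = as_tensor(a)
    sign = np.sign(a.data).astype(np.float32)
    return _make(np.abs(a.data), [(a, lambda g: mul(g, constant(sign)))])


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    if not (_GRAD_ENABLED and a.requires_grad):
        return Tensor(np.maximum(a.data, 0.0))
    mask = (a.data > 0).astype(np.float32)
    return _make(a.data * mask, [(a, lambda g: mul(g, constant(mask)))])


def tanh(a: Tensor) -> Tensor:
    a = as_tensor(a)
    y = np.tanh(a.data)
    out = _make(y, [(a, None)])
    if out.parents:
        # 1 - tanh^2 expressed on the output node keeps higher-order exactness
        out.parents = ((a, lambda g: mul(g, sub(constant(1.0), mul(out, out)))),)
    return out


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)
    data = a.data.sum(axis=axes if axes else None, keepdims=keepdims)

    def vjp(g: Tensor) -> Tensor:
        if not keepdims:
            kept_shape = tuple(
                1 if i in axes else s for i, s in enumerate(a.shape)
            )
            g = reshape(g, kept_shape)
        return broadcast_to(g, a.shape)

    return _make(data, [(a, vjp)])


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), constant(1.0 / n))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data @ b.data,
        [
            (a, lambda g: matmul(g, transpose(b))),
            (b, lambda g: matmul(transpose(a), g)),
        ],
    )


def transpose(a: Tensor) -> Tensor:
    a = as_tensor(a)
    return _make(a.data.T, [(a, lambda g: transpose(g))])


def reshape(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    old = a.shape
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, old))])


def broadcast_to(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    old = a.shape
    return _make(
        np.broadcast_to(a.data, shape),
        [(a, lambda g: _unbroadcast(g, old))],
    )


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    start = 0
    for t in tensors:
        lo, hi = start, start + t.shape[axis]
        parents.append((t, lambda g, lo=lo, hi=hi: slice_axis(g, axis, lo, hi)))
        start = hi
    return _make(data, parents)


def slice_axis(a: Tensor, axis: int, start: int, stop: int) -> Tensor:
    a = as_tensor(a)
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, stop)
    before, after = start, a.shape[axis] - stop
    return _make(
        a.data[tuple(idx)],
        [(a, lambda g: pad_axis(g, axis, before, after))],
    )


def pad_axis(a: Tensor, axis: int, before: int, after: int) -> Tensor:
    a = as_tensor(a)
    widths = [(0, 0)] * a.ndim
    widths[axis] = (before, after)
    stop = before + a.shape[axis]
    return _make(
        np.pad(a.data, widths),
        [(a, lambda g: slice_axis(g, axis, before, stop))],
    )


def instance_norm_affine(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused affine instance normalization over the spatial axes.

    First-order only: the VJPs are evaluated numerically in closed form
    (dx = gamma*s*(g - mean g - c_hat * mean(g*c_hat))) rather than recorded
    as a differentiable sub-graph, which roughly halves the elementwise work
    of a training step. Networks that must be differentiated twice (the
    gradient-penalty critics) compose the same normalization from primitives
    instead.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    xd = x.data
    m = xd.mean(axis=(2, 3, 4), keepdims=True)
    if not (_GRAD_ENABLED and (x.requires_grad or gamma.requires_grad)):
        # allocation-lean inference path (single temporary)
        y = xd - m
        v = (y * y).mean(axis=(2, 3, 4), keepdims=True)
        y *= gamma.data / np.sqrt(v + np.float32(eps))
        y += beta.data
        return Tensor(y)
    c = xd - m
    v = (c * c).mean(axis=(2, 3, 4), keepdims=True)
    s = 1.0 / np.sqrt(v + np.float32(eps))
    chat = c * s
    y = chat * gamma.data + beta.data

    def vjp_x(g: Tensor) -> Tensor:
        gd = g.data * gamma.data
        gm = gd.mean(axis=(2, 3, 4), keepdims=True)
        gc = (gd * chat).mean(axis=(2, 3, 4), keepdims=True)
        return constant(s * (gd - gm - chat * gc))

    def vjp_gamma(g: Tensor) -> Tensor:
        return constant((g.data * chat).sum(axis=(0, 2, 3, 4)).reshape(gamma.shape))

    def vjp_beta(g: Tensor) -> Tensor:
        return constant(g.data.sum(axis=(0, 2, 3, 4)).reshape(beta.shape))

    return _make(y, [(x, vjp_x), (gamma, vjp_gamma), (beta, vjp_beta)])


# ---------------------------------------------------------------------------
# convolution primitives (N, C, D, H, W)
# ---------------------------------------------------------------------------


def _triple(v) -> tuple:
    if isinstance(v, int):
        return (v, v, v)
    return tuple(v)


def _pad_pairs(pad) -> tuple:
    """Normalize padding to ((lo,hi),)*3."""
    pad = _triple(pad)
    return tuple(p if isinstance(p, tuple) else (int(p), int(p)) for p in pad)


def _out_spatial(x_spatial, kshape, stride, pad):
    sd, sh, sw = _triple(stride)
    pp = _pad_pairs(pad)
    return tuple(
        (sz + lo + hi - k) // s + 1
        for sz, k, s, (lo, hi) in zip(x_spatial, kshape, (sd, sh, sw), pp)
    )


def _out_spatial(x_spatial, kshape, stride, pad):
    sd, sh, sw = _triple(stride)
    pp = _pad_pairs(pad)
    return tuple(
        (sz + lo + hi - k) // s + 1
        for sz, k, s, (lo, hi) in zip(x_spatial, kshape, (sd, sh, sw), pp)
    )


def _iter_cols(x: np.ndarray, kshape, stride, pad):
    """Yield ``(n_i, d0, d1, block)`` im2col slabs of bounded memory.

    ``block`` is a contiguous (C*K, (d1-d0)*Ho*Wo) float32 matrix for sample
    ``n_i`` and output-depth rows ``d0:d1``, with the C*K axis laid out as
    (C, kd, kh, kw) to match ``w.reshape(O, -1)``. Filled by one strided
    slice copy per kernel offset, which is far cheaper than gathering
    through an 8-D window view.
    """
    sd, sh, sw = _triple(stride)
    pp = _pad_pairs(pad)
    kd, kh, kw = kshape
    if any(p != (0, 0) for p in pp):
        x = np.pad(x, ((0, 0), (0, 0)) + pp)
    n, c = x.shape[:2]
    do, ho, wo = (
        (sz - k) // s + 1
        for sz, k, s in zip(x.shape[2:], kshape, (sd, sh, sw))
    )
    k_total = kd * kh * kw
    row_bytes = ho * wo * c * k_total * 4
    step = max(1, _COL_CHUNK_BYTES // max(row_bytes, 1))
    h_sl = [slice(b, b + (ho - 1) * sh + 1, sh) for b in range(kh)]
    w_sl = [slice(g, g + (wo - 1) * sw + 1, sw) for g in range(kw)]
    for n_i in range(n):
        for d0 in range(0, do, step):
            d1 = min(do, d0 + step)
            dn = d1 - d0
            block = np.empty((c * k_total, dn * ho * wo), dtype=np.float32)
            bv = block.reshape(c, kd, kh, kw, dn, ho, wo)
            for a in range(kd):
                d_sl = slice(a + d0 * sd, a + (d1 - 1) * sd + 1, sd)
                for b in range(kh):
                    for g in range(kw):
                        bv[:, a, b, g] = x[n_i, :, d_sl, h_sl[b], w_sl[g]]
            yield n_i, d0, d1, block


def _pad_input(x: np.ndarray, pad) -> np.ndarray:
    pp = _pad_pairs(pad)
    if all(p == (0, 0) for p in pp):
        return x
    shape = x.shape[:2] + tuple(n + lo + hi for n, (lo, hi) in zip(x.shape[2:], pp))
    xp = np.zeros(shape, dtype=np.float32)
    xp[
        :,
        :,
        pp[0][0] : pp[0][0] + x.shape[2],
        pp[1][0] : pp[1][0] + x.shape[3],
        pp[2][0] : pp[2][0] + x.shape[4],
    ] = x
    return xp


def _offset_slices(kshape, stride, out_spatial):
    """Per-axis slices of the padded input contributing at each kernel offset."""
    sd, sh, sw = stride
    do, ho, wo = out_spatial
    kd, kh, kw = kshape
    d_sl = [slice(a, a + (do - 1) * sd + 1, sd) for a in range(kd)]
    h_sl = [slice(b, b + (ho - 1) * sh + 1, sh) for b in range(kh)]
    w_sl = [slice(g, g + (wo - 1) * sw + 1, sw) for g in range(kw)]
    return d_sl, h_sl, w_sl


def _conv3d_data(x: np.ndarray, w: np.ndarray, stride, pad) -> np.ndarray:
    n, o = x.shape[0], w.shape[0]
    c = x.shape[1]
    kshape = w.shape[2:]
    out_spatial = _out_spatial(x.shape[2:], kshape, stride, pad)
    do, ho, wo = out_spatial
    strides = _triple(stride)
    pp = _pad_pairs(pad)
    sd = strides[0]
    kd = kshape[0]
    d_in = x.shape[2]
    # three evaluation strategies, chosen per geometry:
    #  - direct numba loops (vectorized over the last axis) for long output
    #    rows; a channel-blocked variant amortizes input-row loads once the
    #    channel product is large;
    #  - per-kernel-offset BLAS products for short output rows;
    # all run over bounded depth slabs so padded working copies stay small.
    use_numba = _kernels.HAVE_NUMBA and wo >= _NUMBA_MIN_W
    blocked = use_numba and c * o >= 256
    wc = np.ascontiguousarray(w) if use_numba else None
    y = np.empty((n, o, do, ho, wo), dtype=np.float32)
    hp = x.shape[3] + pp[1][0] + pp[1][1]
    wp_len = x.shape[4] + pp[2][0] + pp[2][1]
    row_bytes = c * hp * wp_len * 4
    slab = max(1, _CHUNK_BYTES // max(row_bytes, 1))
    d_sl_all, h_sl, w_sl = None, None, None
    for n_i in range(n):
        for d0 in range(0, do, slab):
            d1 = min(do, d0 + slab)
            dn = d1 - d0
            in_lo = d0 * sd - pp[0][0]
            in_hi = (d1 - 1) * sd + kd - 1 - pp[0][0]
            sub = x[n_i : n_i + 1, :, max(0, in_lo) : min(d_in, in_hi + 1)]
            dpad = (max(0, -in_lo), max(0, in_hi - (d_in - 1)))
            subp = _pad_input(sub, (dpad, pp[1], pp[2]))
            if use_numba:
                if subp is sub:
                    subp = np.ascontiguousarray(sub)
                if blocked:
                    _kernels.conv3d_sample_blocked(
                        subp[0], wc, *strides, y[n_i, :, d0:d1]
                    )
                else:
                    _kernels.conv3d_sample(subp[0], wc, *strides, y[n_i, :, d0:d1])
                continue
            if h_sl is None:
                h_sl = [
                    slice(b, b + (ho - 1) * strides[1] + 1, strides[1])
                    for b in range(kshape[1])
                ]
                w_sl = [
                    slice(g, g + (wo - 1) * strides[2] + 1, strides[2])
                    for g in range(kshape[2])
                ]
            p_sub = dn * ho * wo
            acc = np.zeros((o, p_sub), dtype=np.float32)
            for a in range(kd):
                d_sl = slice(a, a + (dn - 1) * sd + 1, sd)
                for b in range(kshape[1]):
                    for g in range(kshape[2]):
                        xv = np.ascontiguousarray(
                            subp[0, :, d_sl, h_sl[b], w_sl[g]]
                        ).reshape(c, p_sub)
                        acc += w[:, :, a, b, g] @ xv
            y[n_i, :, d0:d1] = acc.reshape(o, dn, ho, wo)
    return y


def _conv3d_wgrad_data(x, g, kshape, stride, pad) -> np.ndarray:
    o, c = g.shape[1], x.shape[1]
    n = x.shape[0]
    strides = _triple(stride)
    xp = _pad_input(x, pad)
    out_spatial = g.shape[2:]
    if _kernels.HAVE_NUMBA and g.shape[4] >= _NUMBA_MIN_W_GRAD:
        dw = np.zeros((o, c) + tuple(kshape), dtype=np.float32)
        xc = np.ascontiguousarray(xp)
        gc = np.ascontiguousarray(g)
        for n_i in range(n):
            _kernels.conv3d_wgrad_sample(xc[n_i], gc[n_i], *strides, dw)
        return dw
    p_total = int(np.prod(out_spatial))
    gm = np.ascontiguousarray(g).reshape(n, o, p_total)
    d_sl, h_sl, w_sl = _offset_slices(kshape, strides, out_spatial)
    dw = np.zeros((o, c) + tuple(kshape), dtype=np.float32)
    for a in range(kshape[0]):
        for b in range(kshape[1]):
            for g_i in range(kshape[2]):
                xv = np.ascontiguousarray(xp[:, :, d_sl[a], h_sl[b], w_sl[g_i]])
                xm = xv.reshape(n, c, p_total)
                acc = np.zeros((o, c), dtype=np.float32)
                for n_i in range(n):
                    acc += gm[n_i] @ xm[n_i].T
                dw[:, :, a, b, g_i] = acc
    return dw


def _transpose_class_geometry(r, p, s, k, dz, out_len):
    """Sub-pixel class geometry for one axis of the conv adjoint.

    Output indices i = r + s*q (q = 0..Q-1) receive taps a = a0 + s*m from
    input index j = q + off - m, so each class is a plain stride-1
    correlation of z with the reversed subsampled kernel.
    Returns (a0, m_count, Q, z_lo, pad_l, pad_r) or None if the class has no
    taps (then that output class is all zeros).
    """
    a0 = (r + p) % s
    if a0 >= k:
        return None
    m_count = (k - 1 - a0) // s + 1
    q_count = (out_len - 1 - r) // s + 1 if r < out_len else 0
    if q_count == 0:
        return None
    off = (r + p - a0) // s
    lo = off - (m_count - 1)
    hi = (q_count - 1) + off
    z_lo = max(0, lo)
    z_hi = min(dz - 1, hi)
    pad_l = max(0, -lo)
    pad_r = max(0, hi - (dz - 1))
    return a0, m_count, q_count, (z_lo, z_hi), pad_l, pad_r


def _conv_transpose3d_data(z, w, stride, pad, out_spatial) -> np.ndarray:
    """Adjoint of conv3d(x, w, stride, pad) evaluated at z (x-space output).

    Decomposed into stride**3 sub-pixel classes, each a stride-1 correlation
    with a reversed subsampled kernel — no multiplications against the zeros
    a dilation-based implementation would introduce.
    """
    strides = _triple(stride)
    pp = _pad_pairs(pad)
    n, o = z.shape[0], z.shape[1]
    c = w.shape[1]
    u = np.zeros((n, c) + tuple(out_spatial), dtype=np.float32)
    for rd in range(strides[0]):
        gd = _transpose_class_geometry(
            rd, pp[0][0], strides[0], w.shape[2], z.shape[2], out_spatial[0]
        )
        if gd is None:
            continue
        for rh in range(strides[1]):
            gh = _transpose_class_geometry(
                rh, pp[1][0], strides[1], w.shape[3], z.shape[3], out_spatial[1]
            )
            if gh is None:
                continue
            for rw in range(strides[2]):
                gw = _transpose_class_geometry(
                    rw, pp[2][0], strides[2], w.shape[4], z.shape[4], out_spatial[2]
                )
                if gw is None:
                    continue
                # reversed subsampled kernel, conv orientation (C as out-channels)
                wsub = w[
                    :,
                    :,
                    gd[0] :: strides[0],
                    gh[0] :: strides[1],
                    gw[0] :: strides[2],
                ][:, :, ::-1, ::-1, ::-1]
                wsub = np.ascontiguousarray(wsub.transpose(1, 0, 2, 3, 4))
                zc = z[
                    :,
                    :,
                    gd[3][0] : gd[3][1] + 1,
                    gh[3][0] : gh[3][1] + 1,
                    gw[3][0] : gw[3][1] + 1,
                ]
                pads = ((gd[4], gd[5]), (gh[4], gh[5]), (gw[4], gw[5]))
                res = _conv3d_data(zc, wsub, 1, pads)
                u[:, :, rd :: strides[0], rh :: strides[1], rw :: strides[2]] = res
    return u


def conv3d(x: Tensor, w: Tensor, stride=1, pad=0) -> Tensor:
    """3D cross-correlation of ``x`` (N,C,D,H,W) with ``w`` (O,C,kd,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    in_spatial = x.shape[2:]
    data = _conv3d_data(x.data, w.data, stride, pad)
    return _make(
        data,
        [
            (x, lambda g: conv_transpose3d(g, w, stride, pad, in_spatial)),
            (w, lambda g: conv3d_wgrad(x, g, w.shape[2:], stride, pad)),
        ],
    )


def conv_transpose3d(z: Tensor, w: Tensor, stride=1, pad=0, out_spatial=None) -> Tensor:
    """Adjoint of :func:`conv3d` with the same ``w``/``stride``/``pad``.

    Maps the conv's output space (channels O) back to its input space
    (channels C); ``out_spatial`` resolves the stride ambiguity.
    """
    z, w = as_tensor(z), as_tensor(w)
    if out_spatial is None:
        sd, sh, sw = _triple(stride)
        pp = _pad_pairs(pad)
        out_spatial = tuple(
            (z.shape[2 + i] - 1) * s - plo - phi + w.shape[2 + i]
            for i, (s, (plo, phi)) in enumerate(zip((sd, sh, sw), pp))
        )
    out_spatial = tuple(out_spatial)
    z_spatial = z.shape[2:]
    data = _conv_transpose3d_data(z.data, w.data, stride, pad, out_spatial)
    return _make(
        data,
        [
            (z, lambda g: conv3d(g, w, stride, pad)),
            (w, lambda g: conv3d_wgrad(g, z, w.shape[2:], stride, pad)),
        ],
    )


def conv3d_wgrad(x: Tensor, g: Tensor, kshape, stride=1, pad=0) -> Tensor:
    """Gradient of conv3d w.r.t. its weights: correlate ``x`` with ``g``."""
    x, g = as_tensor(x), as_tensor(g)
    kshape = tuple(kshape)
    in_spatial = x.shape[2:]
    data = _conv3d_wgrad_data(x.data, g.data, kshape, stride, pad)
    return _make(
        data,
        [
            (x, lambda v: conv_transpose3d(g, v, stride, pad, in_spatial)),
            (g, lambda v: conv3d(x, v, stride, pad)),
        ],
    )


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------


def _toposort(root: Tensor) -> list:
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order  # parents before children


def grad(output: Tensor, wrt: Iterable[Tensor], cotangent: Tensor | None = None) -> list:
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``wrt``.

    The returned gradients are themselves graph nodes, so they can be
    differentiated again (used by the WGAN gradient penalty).
    """
    wrt = list(wrt)
    if cotangent is None:
        cotangent = constant(np.ones(output.shape, dtype=np.float32))
    cotangents: dict[int, Tensor] = {id(output): cotangent}
    for node in reversed(_toposort(output)):
        ct = cotangents.pop(id(node), None)
        if ct is None:
            continue
        if any(id(node) == id(w) for w in wrt):
            cotangents[id(node)] = ct  # keep requested leaves
        for parent, vjp in node.parents:
            contrib = vjp(ct)
            prev = cotangents.get(id(parent))
            cotangents[id(parent)] = contrib if prev is None else add(prev, contrib)
    out = []
    for w in wrt:
        g = cotangents.get(id(w))
        if g is None:
            g = constant(np.zeros(w.shape, dtype=np.float32))
        out.append(g)
    return out
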