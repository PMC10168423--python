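"""Numba-accelerated direct 3D convolution kernels.

The channel counts in this pipeline are small (4-320), which makes im2col +
BLAS matrix products memory-bound; direct loops that vectorize over the last
spatial axis are several times faster on one CPU core. These kernels are
pure implementations of the same contracts as the numpy paths in
:mod:`surf2vol.autodiff`, which fall back automatically when numba is not
importable.

All kernels operate on one sample: ``xp`` is the already zero-padded input
(C, Dp, Hp, Wp); weights are (O, C, kd, kh, kw). The common 3x3x3 / stride-1
inner case is unrolled explicitly so the last-axis loop vectorizes into FMAs.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by the dispatch tests
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


@njit(cache=True, fastmath=True)
def conv3d_sample(xp, w, sd, sh, sw, y):
    """y[o,d,h,t] = sum_{c,a,b,g} w[o,c,a,b,g] * xp[c, d*sd+a, h*sh+b, t*sw+g]."""
    o_n, c_n, kd, kh, kw = w.shape
    do, ho, wo = y.shape[1], y.shape[2], y.shape[3]
    for o in range(o_n):
        for d in range(do):
            for h in range(ho):
                acc = np.zeros(wo, dtype=np.float32)
                for c in range(c_n):
                    for a in range(kd):
                        xr = xp[c, d * sd + a]
                        for b in range(kh):
                            row = xr[h * sh + b]
                            wr = w[o, c, a, b]
                            if sw == 1 and kw == 3:
                                w0, w1, w2 = wr[0], wr[1], wr[2]
                                for t in range(wo):
                                    acc[t] += w0 * row[t] + w1 * row[t + 1] + w2 * row[t + 2]
                            elif sw == 1:
                                for g in range(kw):
                                    wv = wr[g]
                                    rg = row[g:]
                                    for t in range(wo):
                                        acc[t] += wv * rg[t]
                            else:
                                for g in range(kw):
                                    wv = wr[g]
                                    for t in range(wo):
                                        acc[t] += wv * row[t * sw + g]
                y[o, d, h, :] = acc


@njit(cache=True, fastmath=True)
def conv3d_sample_blocked(xp, w, sd, sh, sw, y):
    """As :func:`conv3d_sample` but accumulating every output channel while
    an input row is hot in cache — much faster when C*O is large, at the
    price of an (O, Wo) accumulator per output row."""
    o_n, c_n, kd, kh, kw = w.shape
    do, ho, wo = y.shape[1], y.shape[2], y.shape[3]
    acc = np.empty((o_n, wo), dtype=np.float32)
    for d in range(do):
        for h in range(ho):
            acc[:, :] = 0.0
            for c in range(c_n):
                for a in range(kd):
                    xr = xp[c, d * sd + a]
                    for b in range(kh):
                        row = xr[h * sh + b]
                        for o in range(o_n):
                            wr = w[o, c, a, b]
                            ao = acc[o]
                            if kw == 3 and sw == 1:
                                w0, w1, w2 = wr[0], wr[1], wr[2]
                                for t in range(wo):
                                    ao[t] += w0 * row[t] + w1 * row[t + 1] + w2 * row[t + 2]
                            elif sw == 1:
                                for g in range(kw):
                                    wv = wr[g]
                                    rg = row[g:]
                                    for t in range(wo):
                                        ao[t] += wv * rg[t]
                            else:
                                for g in range(kw):
                                    wv = wr[g]
                                    for t in range(wo):
                                        ao[t] += wv * row[t * sw + g]
            for o in range(o_n):
                y[o, d, h, :] = acc[o]


@njit(cache=True, fastmath=True)
def conv3d_wgrad_sample(xp, gr, sd, sh, sw, dw):
    """dw[o,c,a,b,g] += sum_{d,h,t} gr[o,d,h,t] * xp[c, d*sd+a, h*sh+b, t*sw+g]."""
    o_n, do, ho, wo = gr.shape
    c_n, kd, kh, kw = dw.shape[1], dw.shape[2], dw.shape[3], dw.shape[4]
    for o in range(o_n):
        for c in range(c_n):
            for a in range(kd):
                for b in range(kh):
                    if sw == 1 and kw == 3:
                        s0 = np.float32(0.0)
                        s1 = np.float32(0.0)
                        s2 = np.float32(0.0)
                        for d in range(do):
                            xr = xp[c, d * sd + a]
                            for h in range(ho):
                                grow = gr[o, d, h]
                                row = xr[h * sh + b]
                                for t in range(wo):
                                    gt = grow[t]
                                    s0 += gt * row[t]
                                    s1 += gt * row[t + 1]
                                    s2 += gt * row[t + 2]
                        dw[o, c, a, b, 0] += s0
                        dw[o, c, a, b, 1] += s1
                        dw[o, c, a, b, 2] += s2
                    else:
                        for g in range(kw):
                            s = np.float32(0.0)
                            for d in range(do):
                                xr = xp[c, d * sd + a]
                                for h in range(ho):
                                    grow = gr[o, d, h]
                                    row = xr[h * sh + b]
                                    for t in range(wo):
                                        s += grow[t] * row[t * sw + g]
                            dw[o, c, a, b, g] += s
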