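"""Differentiable tensor operations used by the segmentation network.

All functions take and return :class:`~mscdunet.nn.autodiff.Var` nodes
(plain arrays are wrapped as constants) and preserve the input dtype.
Spatial tensors are laid out ``(batch, channels, D, H, W)``.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Var, as_var

__all__ = [
    "relu",
    "concat",
    "conv3d",
    "conv_transpose2",
    "max_pool3d",
    "avg_pool3d",
    "upsample_trilinear",
    "batch_norm",
    "weighted_sum",
    "weighted_cross_entropy",
    "softmax",
    "log_softmax",
]


# ---------------------------------------------------------------------------
# correlation core (stride 1)

def _im2col(x, k, pad):
    """Return (cols, out_shape): cols is (B, C*k^3, Do*Ho*Wo).

    Channel-major column layout: the copy walks contiguous spatial
    rows of the padded source, and the GEMM output needs no transpose.
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    b, c = x.shape[:2]
    if k == 1:  # pointwise conv: columns are just a reshape, no copy
        return x.reshape(b, c, -1), x.shape[2:]
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    b, c, do, ho, wo = win.shape[:5]
    cols = np.ascontiguousarray(win.transpose(0, 1, 5, 6, 7, 2, 3, 4))
    return cols.reshape(b, c * k ** 3, do * ho * wo), (do, ho, wo)


def _corr3d(x, w, pad, cols=None):
    """Stride-1 cross-correlation of x (B,C,D,H,W) with w (O,C,k,k,k)."""
    k = w.shape[2]
    if cols is None:
        cols, out_sp = _im2col(x, k, pad)
    else:
        cols, out_sp = cols
    out = np.matmul(w.reshape(w.shape[0], -1), cols)
    return out.reshape(x.shape[0], w.shape[0], *out_sp)


def conv3d(x, w, b=None, pad=None):
    """3-D convolution (cross-correlation), stride 1.

    ``pad`` defaults to (k-1)//2 which preserves the spatial extent for
    odd kernels (the network uses k=3 and k=1 only).
    """
    xv, wv = as_var(x), as_var(w)
    k = wv.value.shape[2]
    if pad is None:
        pad = (k - 1) // 2
    cols, out_sp = _im2col(xv.value, k, pad)
    out = _corr3d(xv.value, wv.value, pad, cols=(cols, out_sp))
    parents = []

    def grad_x(g, _w=wv, _k=k, _pad=pad):
        wt = np.ascontiguousarray(
            _w.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        return _corr3d(g, wt, _k - 1 - _pad)

    def grad_w(g, _cols=cols, _shape=wv.value.shape):
        o = _shape[0]
        gf = g.reshape(g.shape[0], o, -1)
        return np.matmul(gf, _cols.transpose(0, 2, 1)).sum(axis=0).reshape(_shape)

    parents.append((xv, grad_x))
    parents.append((wv, grad_w))
    if b is not None:
        bv = as_var(b)
        out = out + bv.value.reshape(1, -1, 1, 1, 1)
        parents.append((bv, lambda g: g.sum(axis=(0, 2, 3, 4))))
    return Var(out, parents)


def conv_transpose2(x, w, b=None):
    """Transposed convolution with 2x2x2 kernel and stride 2.

    Kernel and stride coincide, so output voxels are disjoint
    interleavings: out[., o, 2d+r, 2h+s, 2w+t] = sum_c x[., c, d, h, w] * w[c, o, r, s, t].
    """
    xv, wv = as_var(x), as_var(w)
    a = xv.value
    bsz, _, d, h, wd = a.shape
    o = wv.value.shape[1]
    t = np.einsum("bcdhw,corst->bodrhswt", a, wv.value, optimize=True)
    out = t.reshape(bsz, o, 2 * d, 2 * h, 2 * wd)
    parents = [
        (
            xv,
            lambda g: np.einsum(
                "bodrhswt,corst->bcdhw",
                g.reshape(bsz, o, d, 2, h, 2, wd, 2),
                wv.value,
                optimize=True,
            ),
        ),
        (
            wv,
            lambda g: np.einsum(
                "bcdhw,bodrhswt->corst",
                a,
                g.reshape(bsz, o, d, 2, h, 2, wd, 2),
                optimize=True,
            ),
        ),
    ]
    if b is not None:
        bv = as_var(b)
        out = out + bv.value.reshape(1, -1, 1, 1, 1)
        parents.append((bv, lambda g: g.sum(axis=(0, 2, 3, 4))))
    return Var(out, parents)


# ---------------------------------------------------------------------------
# pooling (kernel k, stride 2, symmetric padding (k-1)//2)

def _pool_windows(a, k, pad_value):
    q = (k - 1) // 2
    ap = np.pad(a, ((0, 0), (0, 0)) + ((q, q),) * 3, constant_values=pad_value)
    win = sliding_window_view(ap, (k, k, k), axis=(2, 3, 4))[:, :, ::2, ::2, ::2]
    return win, q


def max_pool3d(x, k):
    """Max pooling, kernel k, stride 2; out-of-grid treated as -inf."""
    xv = as_var(x)
    a = xv.value
    bsz, c, d, h, w = a.shape
    _check_pool_extent(a.shape[2:], k)
    win, q = _pool_windows(a, k, -np.inf)
    do, ho, wo = win.shape[2:5]
    wf = win.reshape(bsz, c, do, ho, wo, k ** 3)
    idx = wf.argmax(-1)
    out = np.take_along_axis(wf, idx[..., None], -1)[..., 0]

    def grad_x(g):
        r, rem = np.divmod(idx, k * k)
        s, t = np.divmod(rem, k)
        dd = 2 * np.arange(do)[:, None, None] + r - q
        hh = 2 * np.arange(ho)[None, :, None] + s - q
        ww = 2 * np.arange(wo)[None, None, :] + t - q
        bi = np.arange(bsz)[:, None, None, None, None]
        ci = np.arange(c)[None, :, None, None, None]
        flat = (((bi * c + ci) * d + dd) * h + hh) * w + ww
        gx = np.zeros(bsz * c * d * h * w, dtype=g.dtype)
        np.add.at(gx, flat.ravel(), g.ravel())
        return gx.reshape(a.shape)

    return Var(out, [(xv, grad_x)])


def avg_pool3d(x, k):
    """Average pooling, kernel k, stride 2; averages over in-grid voxels only."""
    xv = as_var(x)
    a = xv.value
    bsz, c, d, h, w = a.shape
    _check_pool_extent(a.shape[2:], k)
    win, q = _pool_windows(a, k, 0.0)
    do, ho, wo = win.shape[2:5]
    sums = win.reshape(bsz, c, do, ho, wo, k ** 3).sum(-1)
    ones = np.ones((1, 1, d, h, w), dtype=a.dtype)
    cwin, _ = _pool_windows(ones, k, 0.0)
    counts = cwin.reshape(1, 1, do, ho, wo, k ** 3).sum(-1)
    out = sums / counts

    def grad_x(g):
        gc = g / counts
        gp = np.zeros(
            (bsz, c, d + 2 * q, h + 2 * q, w + 2 * q), dtype=g.dtype
        )
        for r, s, t in product(range(k), repeat=3):
            gp[:, :, r : r + 2 * do : 2, s : s + 2 * ho : 2, t : t + 2 * wo : 2] += gc
        return gp[:, :, q : q + d, q : q + h, q : q + w]

    return Var(out, [(xv, grad_x)])


def _check_pool_extent(spatial, k):
    for e in spatial:
        if e % 2 != 0:
            raise ValueError(
                f"pooling requires even spatial extents, got {tuple(spatial)}"
            )
        if e < k:
            raise ValueError(f"spatial extent {e} smaller than pooling kernel {k}")


# ---------------------------------------------------------------------------
# upsampling

def _interp_matrix(d, f, dtype):
    out = f * d
    pos = np.clip((np.arange(out) + 0.5) / f - 0.5, 0, d - 1)
    lo = np.floor(pos).astype(np.intp)
    hi = np.minimum(lo + 1, d - 1)
    frac = (pos - lo).astype(dtype)
    m = np.zeros((out, d), dtype=dtype)
    np.add.at(m, (np.arange(out), lo), 1 - frac)
    np.add.at(m, (np.arange(out), hi), frac)
    return m


def _apply_axis(a, m, axis):
    return np.moveaxis(np.tensordot(m, a, axes=(1, axis)), 0, axis)


def upsample_trilinear(x, factor):
    """Trilinear upsampling by an integer factor (half-voxel aligned)."""
    xv = as_var(x)
    a = xv.value
    if factor == 1:
        return xv
    mats = [_interp_matrix(a.shape[ax + 2], factor, a.dtype) for ax in range(3)]
    out = a
    for ax, m in enumerate(mats):
        out = _apply_axis(out, m, ax + 2)

    def grad_x(g):
        for ax in (2, 1, 0):
            g = _apply_axis(g, mats[ax].T, ax + 2)
        return g

    return Var(out, [(xv, grad_x)])


# ---------------------------------------------------------------------------
# normalization / activations / glue

def batch_norm(x, gamma, beta, state, training, momentum=0.1, eps=1e-5):
    """Channel-wise batch normalization with running statistics.

    ``state`` is a dict holding ``mean``/``var`` running arrays, updated
    in place in training mode.
    """
    xv, gv, bv = as_var(x), as_var(gamma), as_var(beta)
    a = xv.value
    axes = (0, 2, 3, 4)
    if training:
        m = a.mean(axes)
        v = a.var(axes)
        state["mean"] = (1 - momentum) * state["mean"] + momentum * m
        state["var"] = (1 - momentum) * state["var"] + momentum * v
    else:
        m, v = state["mean"], state["var"]
    std = np.sqrt(v + eps).astype(a.dtype)
    shape = (1, -1, 1, 1, 1)
    xhat = (a - m.reshape(shape)) / std.reshape(shape)
    out = gv.value.reshape(shape) * xhat + bv.value.reshape(shape)

    if training:

        def grad_x(g):
            dxh = g * gv.value.reshape(shape)
            mu1 = dxh.mean(axes).reshape(shape)
            mu2 = (dxh * xhat).mean(axes).reshape(shape)
            return (dxh - mu1 - xhat * mu2) / std.reshape(shape)

    else:

        def grad_x(g):
            return g * (gv.value / std).reshape(shape)

    parents = [
        (xv, grad_x),
        (gv, lambda g: (g * xhat).sum(axes)),
        (bv, lambda g: g.sum(axes)),
    ]
    return Var(out, parents)


def relu(x):
    xv = as_var(x)
    mask = xv.value > 0
    return Var(
        np.where(mask, xv.value, 0),
        [(xv, lambda g: np.where(mask, g, 0))],
    )


def concat(xs, axis=1):
    vs = [as_var(x) for x in xs]
    out = np.concatenate([v.value for v in vs], axis=axis)
    parents = []
    off = 0
    for v in vs:
        n = v.value.shape[axis]
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(off, off + n)
        parents.append((v, lambda g, _sl=tuple(sl): g[_sl]))
        off += n
    return Var(out, parents)


def weighted_sum(xs, w):
    """sum_h w[h] * xs[h] with a learnable weight vector w."""
    vs = [as_var(x) for x in xs]
    wv = as_var(w)
    if len(vs) != wv.value.shape[0]:
        raise ValueError("weight length does not match number of terms")
    out = sum(wv.value[i] * vs[i].value for i in range(len(vs)))
    parents = [
        (v, lambda g, _i=i: wv.value[_i] * g) for i, v in enumerate(vs)
    ]
    parents.append(
        (
            wv,
            lambda g: np.array(
                [(g * v.value).sum() for v in vs], dtype=wv.value.dtype
            ),
        )
    )
    return Var(out, parents)


# ---------------------------------------------------------------------------
# softmax / losses

def log_softmax(a, axis=1):
    m = a.max(axis=axis, keepdims=True)
    s = a - m
    return s - np.log(np.exp(s).sum(axis=axis, keepdims=True))


def softmax(a, axis=1):
    e = np.exp(a - a.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(logits, target, omega):
    """Class-weighted cross-entropy, averaged over all voxels.

    ``target`` is an integer label array shaped like the logits without
    the channel axis; ``omega[c]`` weights voxels whose true class is c.
    """
    lv = as_var(logits)
    a = lv.value
    n_classes = a.shape[1]
    target = np.asarray(target)
    if target.min() < 0 or target.max() >= n_classes:
        raise ValueError(
            f"target labels must lie in [0, {n_classes - 1}], "
            f"got range [{target.min()}, {target.max()}]"
        )
    omega = np.asarray(omega, dtype=a.dtype)
    if omega.shape[0] != n_classes:
        raise ValueError("omega length must equal the number of classes")
    logp = log_softmax(a)
    wvox = omega[target]
    n = target.size
    picked = np.take_along_axis(logp, target[:, None], axis=1)[:, 0]
    loss = -(wvox * picked).sum() / n

    def grad(g):
        p = softmax(a)
        dl = p * wvox[:, None]
        idx = target[:, None]
        np.put_along_axis(
            dl, idx, np.take_along_axis(dl, idx, 1) - wvox[:, None], 1
        )
        return (g / n) * dl

    return Var(np.asarray(loss), [(lv, grad)])
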